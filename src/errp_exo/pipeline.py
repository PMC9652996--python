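"""End-to-end pipeline: simulate -> preprocess -> decode -> report.

Canonical run layout under the output directory:

    protocol/   per-subject protocol.yaml + events.tsv
    raw/        continuous streams (only with ``write_raw``; large)
    epochs/     per-subject, per-modality epoch containers
    decoding/   per-subject, per-modality/scheme DecodingResult JSON
    report/     group accuracy table, grand averages, test outcomes

Every artifact is stamped with the master seed and a config hash; re-runs
with the same config are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from errp_exo import io as eio
from errp_exo.config import PipelineConfig, config_echo
from errp_exo.decoding import DecodingResult, decode_session
from errp_exo.montage import build_montage
from errp_exo.preprocess import preprocess_session
from errp_exo.protocol import ProtocolTiming, build_protocol, trajectory_accuracy
from errp_exo.stats import compare_conditions, power_extrapolation
from errp_exo.synth import NoiseConfig, synth_session

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _result_doc(res: DecodingResult, seed: int, chash: str) -> dict:
    return {
        "modality": res.modality, "scheme": res.scheme,
        "mean_accuracy": res.mean_accuracy, "sem_accuracy": res.sem_accuracy,
        "fold_accuracies": res.fold_accuracies.tolist(),
        "confusion": res.confusion.tolist(),
        "n_folds": res.n_folds, "n_repeats": res.n_repeats,
        "seed": seed, "config_hash": chash,
    }


def _binomial_chance(acc_percent: float, n_trials: int, inflation: float = 2.5) -> bool:
    """Chance-level flag for a cross-validated accuracy.

    Fold dependence and classifier overfitting make CV accuracy on null data
    spread wider than a binomial proportion (and sit slightly above 50%), so
    the 1.96-sigma binomial half width is inflated by a fixed factor
    calibrated against label-permutation runs of the default pipeline.
    """
    half_width = inflation * 196.0 * np.sqrt(0.25 / max(n_trials, 1))
    return abs(acc_percent - 50.0) <= half_width


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline; returns the artifact directory."""
    out = Path(out_dir)
    chash = eio.config_hash(config_echo(config))
    for sub in ("protocol", "epochs", "decoding", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(
        {"config": config_echo(config), "hash": chash, "seed": config.seed}, indent=1))
    logger.info("pipeline start: seed=%d hash=%s", config.seed, chash)

    gen = config.generator
    noise = NoiseConfig() if gen.noise_rms_uv is None and gen.blink_rate_per_min is None else \
        NoiseConfig(
            rms_uv=gen.noise_rms_uv if gen.noise_rms_uv is not None else NoiseConfig.rms_uv,
            blink_rate_per_min=(gen.blink_rate_per_min
                                if gen.blink_rate_per_min is not None
                                else NoiseConfig.blink_rate_per_min),
        )
    montage = build_montage()
    seeds = np.random.SeedSequence(config.seed).spawn(gen.n_subjects)

    acc_rows, traj_rows = [], []
    fig_data = {"cz_err": [], "cz_non": [], "times": None,
                "pool_err": [], "pool_non": [], "channels": None}
    for i, ss in enumerate(seeds):
        subject = i + 1
        try:
            protocol = None
            if gen.episodes_per_block or gen.events_per_episode:
                base = build_protocol(int(ss.generate_state(1)[0] % (2**31)))
                protocol = dataclasses.replace(
                    base,
                    episodes_per_block=gen.episodes_per_block or base.episodes_per_block,
                    events_per_episode=tuple(gen.events_per_episode or base.events_per_episode),
                )
            rec = synth_session(subject, ss, protocol=protocol, noise_cfg=noise,
                                effect_scale=gen.effect_scale)
        except Exception as e:  # noqa: BLE001
            raise StageError("simulate", e) from e
        logger.info("subject %d: %d events, %.0f s", subject, len(rec.events), rec.duration)
        eio.write_protocol_yaml(rec.protocol, out / "protocol" / f"sub-{subject}_protocol.yaml")
        eio.write_events_tsv(rec.events, out / "protocol" / f"sub-{subject}_events.tsv")
        if config.write_raw:
            eio.write_recording(rec, out / "raw" / f"sub-{subject}")
        for scheme in ("unassisted", "gravity", "myoprocessor"):
            evs = [e for e in rec.events if e.scheme == scheme]
            traj_rows.append({"subject": subject, "condition": scheme,
                              "accuracy": trajectory_accuracy(evs, rec.protocol)})

        try:
            epoch_sets = preprocess_session(rec, montage, config.preprocess)
        except Exception as e:  # noqa: BLE001
            raise StageError("preprocess", e) from e
        for mod, eps in epoch_sets.items():
            eio.write_epochs(eps, out / "epochs" / f"sub-{subject}_{mod}")
        if config.make_figures:
            _collect_figure_data(fig_data, epoch_sets["eeg"])

        try:
            for mod in config.decoder.modalities:
                for scheme in config.decoder.schemes:
                    res = decode_session(
                        epoch_sets, mod, scheme,
                        n_folds=config.decoder.n_folds,
                        n_repeats=config.decoder.n_repeats,
                        seed=int(np.random.SeedSequence([config.seed, subject]).generate_state(1)[0] % (2**31)),
                    )
                    doc = _result_doc(res, config.seed, chash)
                    doc["subject"] = subject
                    name = f"sub-{subject}_{mod}_{scheme}.json"
                    (out / "decoding" / name).write_text(json.dumps(doc, indent=1))
                    acc_rows.append({"subject": subject, "modality": mod,
                                     "scheme": scheme, "accuracy": res.mean_accuracy,
                                     "n_trials": int(res.confusion.sum() // res.n_repeats)})
        except Exception as e:  # noqa: BLE001
            raise StageError("decode", e) from e

    try:
        report = build_report(pd.DataFrame(acc_rows), pd.DataFrame(traj_rows))
        report["seed"], report["config_hash"] = config.seed, chash
        (out / "report" / "report.json").write_text(json.dumps(report, indent=1))
        pd.DataFrame(acc_rows).to_csv(out / "report" / "accuracies.tsv", sep="\t", index=False)
        pd.DataFrame(traj_rows).to_csv(out / "report" / "trajectory_accuracy.tsv",
                                       sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("report", e) from e
    if config.make_figures:
        try:
            _write_figures(out / "report", fig_data, pd.DataFrame(acc_rows))
        except Exception as e:  # noqa: BLE001
            raise StageError("report", e) from e
    logger.info("pipeline done: %s", out)
    return out


def _collect_figure_data(store: dict, eeg_epochs) -> None:
    """Accumulate Cz grand-average curves and decimated error-block epochs."""
    from scipy.signal import decimate

    eb = eeg_epochs.error_blocks()
    cz = list(eb.channel_names).index("Cz")
    store["cz_err"].append(eb.data[eb.labels == 1, cz].mean(0))
    store["cz_non"].append(eb.data[eb.labels == 0, cz].mean(0))
    store["times"] = eeg_epochs.times
    store["channels"] = eb.channel_names
    dec8 = decimate(eb.data.astype(np.float64), 8, ftype="fir",
                    axis=-1, zero_phase=True).astype(np.float32)
    store["pool_err"].append(dec8[eb.labels == 1])
    store["pool_non"].append(dec8[eb.labels == 0])


def _write_figures(report_dir: Path, store: dict, acc: pd.DataFrame) -> None:
    """Grand-average ERP plot, channel x time Tukey mask, accuracy bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from errp_exo.stats import tukey_hsd_map

    t = store["times"]
    err = np.mean(store["cz_err"], axis=0)
    non = np.mean(store["cz_non"], axis=0)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(t, err, label="error", color="crimson")
    ax.plot(t, non, label="non-error", color="steelblue")
    ax.plot(t, err - non, label="difference", color="black", ls="--")
    ax.axhline(0, color="gray", lw=0.5)
    ax.set(xlabel="time post onset (s)", ylabel="amplitude (uV)",
           title="Grand-average ERP at Cz (error blocks)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(report_dir / "grand_average_erp.png", dpi=120)
    plt.close(fig)

    pool_err = np.concatenate(store["pool_err"])
    pool_non = np.concatenate(store["pool_non"])
    mask = tukey_hsd_map(error_data=pool_err, nonerror_data=pool_non, alpha=0.05)
    fig, ax = plt.subplots(figsize=(8, 5))
    t8 = np.linspace(t[0], t[-1], mask.shape[1])
    ax.imshow(mask, aspect="auto", cmap="Greys", interpolation="nearest",
              extent=[t8[0], t8[-1], mask.shape[0] - 0.5, -0.5])
    ax.set_yticks(range(len(store["channels"])))
    ax.set_yticklabels(store["channels"], fontsize=6)
    ax.set(xlabel="time post onset (s)",
           title="Tukey HSD p<0.05: error vs non-error")
    fig.tight_layout()
    fig.savefig(report_dir / "tukey_mask.png", dpi=120)
    plt.close(fig)

    comb = acc[acc["scheme"] == "combined"]
    stats = comb.groupby("modality")["accuracy"].agg(["mean", "sem"]).fillna(0.0)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(stats.index, stats["mean"], yerr=stats["sem"], capsize=4,
           color=["#4477aa", "#ee6677", "#228833"][: len(stats)])
    ax.axhline(50, color="gray", ls=":", lw=1)
    ax.set(ylabel="decoding accuracy (%)", ylim=(0, 100),
           title="Error decoding by modality (mean +/- SEM)")
    fig.tight_layout()
    fig.savefig(report_dir / "accuracy_bars.png", dpi=120)
    plt.close(fig)


def build_report(acc: pd.DataFrame, traj: pd.DataFrame) -> dict:
    """Group summary: grand means +/- SEM, chance flags, scheme contrasts."""
    report: dict = {"modalities": {}, "trajectory": {}}
    for mod, g in acc[acc["scheme"] == "combined"].groupby("modality"):
        vals = g["accuracy"].to_numpy(dtype=float)
        n_trials = int(g["n_trials"].sum()) if "n_trials" in g else 0
        report["modalities"][mod] = {
            "grand_mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
            "per_subject": vals.tolist(),
            "chance_level": bool(_binomial_chance(float(vals.mean()), n_trials)),
        }
    for cond, g in traj.groupby("condition"):
        vals = g["accuracy"].to_numpy(dtype=float)
        report["trajectory"][cond] = {"mean": float(vals.mean()),
                                      "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
    if len(traj["condition"].unique()) >= 2 and traj["subject"].nunique() >= 2:
        try:
            comp = compare_conditions(traj)
            report["trajectory_tukey"] = comp.tukey_table.to_dict(orient="records")
        except ValueError:
            pass
    wide = acc[(acc["scheme"].isin(["gravity", "myoprocessor"]))
               & (acc["modality"] == "eeg")].pivot_table(
        index="subject", columns="scheme", values="accuracy")
    if {"gravity", "myoprocessor"} <= set(wide.columns) and len(wide.dropna()) >= 2:
        comp = compare_conditions(
            acc[acc["modality"] == "eeg"], condition_col="scheme")
        report["eeg_scheme_paired_t"] = comp.paired_t
        report["eeg_scheme_lilliefors_p"] = comp.lilliefors_p
        g = wide.dropna()
        report["power_extrapolation_p"] = power_extrapolation(
            g["gravity"].to_numpy(), g["myoprocessor"].to_numpy(), 2)
    return report
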