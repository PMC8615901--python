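"""End-to-end pipeline: simulate -> preprocess -> TFR -> connectivity -> network -> stats.

A :class:`PipelineConfig` carries every analysis parameter with the study's
values as defaults (±200 µV artifact threshold, 15% bad-channel trial rule,
5-trial minimum, 0.3 Hz high-pass, 6-9 Hz band, 400-800 ms window, baseline
-600..-100 ms).  :func:`run` executes the stages in a fixed order, writes all
tables as CSV, and records a manifest of output files with content hashes;
identical config + seed reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn_mod
from . import network as net_mod
from . import preprocessing as prep
from . import stats as stats_mod
from . import synthetic, timefreq
from .epochs import EMOTIONS

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run", "PipelineError"]


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the study's analysis values."""

    input: str = "simulate"  # "simulate" or a directory of epoch containers
    n_dynamic: int = 19
    n_static: int = 19
    n_trials_per_emotion: int = 8
    n_channels: int = 128
    n_regions: int = 10
    artifact_rate: float = 0.1
    subject_sd: float = 0.3
    threshold_uv: float = 200.0
    max_bad_fraction: float = 0.15
    min_trials: int = 5
    highpass_hz: float = 0.3
    band: tuple[float, float] = (6.0, 9.0)
    analysis_window: tuple[float, float] = (400.0, 800.0)
    baseline: tuple[float, float] = (-600.0, -100.0)
    n_cycles: float = 5.0
    trim_ms: float = 400.0
    spline_order: int = 4
    spline_terms: int = 50
    spline_reg: float = 1e-5
    epsilon: float = 1e-6
    alpha: float = 0.05
    connectivity_channels: str = "all"  # "all" or "regions"
    connectivity_window: tuple[float, float] = (0.0, 1000.0)
    seed: int = 0
    outdir: str = "munet_out"
    stats_clusters: tuple[str, str] = ("C3", "C4")

    def study_config(self) -> synthetic.StudyConfig:
        return synthetic.StudyConfig(
            n_dynamic=self.n_dynamic,
            n_static=self.n_static,
            n_trials_per_emotion=self.n_trials_per_emotion,
            n_channels=self.n_channels,
            n_regions=self.n_regions,
            artifact_rate=self.artifact_rate,
            subject_sd=self.subject_sd,
        )


def _parse_window(value, name: str) -> tuple[float, float]:
    if isinstance(value, str):
        sep = "-" if "-" in value.strip("-") else ","
        parts = value.replace("(", "").replace(")", "").strip()
        # allow "6-9" and "400,800"; leading minus kept with the number
        if sep == "-":
            chunks = []
            buf = ""
            for ch in parts:
                if ch == "-" and buf not in ("", "-"):
                    chunks.append(buf)
                    buf = ""
                else:
                    buf += ch
            chunks.append(buf)
            parts = chunks
        else:
            parts = parts.split(",")
        value = [float(p) for p in parts]
    lo, hi = (float(value[0]), float(value[1]))
    if not lo < hi:
        raise ConfigError(f"{name} must be an increasing pair, got ({lo}, {hi})")
    return lo, hi


def validate_config(config: dict | PipelineConfig | None) -> PipelineConfig:
    """Normalise a raw config mapping, filling defaults and rejecting errors.

    Unknown keys are rejected (listing the offenders); window-like fields
    accept "lo-hi" strings; thresholds must be positive.
    """
    if config is None:
        config = {}
    if isinstance(config, PipelineConfig):
        config = asdict(config)
    known = {f: getattr(PipelineConfig(), f) for f in PipelineConfig.__dataclass_fields__}
    unknown = sorted(set(config) - set(known))
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    merged = {**known, **config}
    for key in ("band", "analysis_window", "baseline", "connectivity_window"):
        merged[key] = _parse_window(merged[key], key)
    cfg = PipelineConfig(**merged)
    for key in ("threshold_uv", "highpass_hz", "epsilon", "trim_ms"):
        val = getattr(cfg, key)
        if isinstance(val, str) or not val > 0:
            raise ConfigError(f"{key} must be a positive number, got {val!r}")
    if not 0 < cfg.max_bad_fraction < 1:
        raise ConfigError("max_bad_fraction must be in (0, 1)")
    if cfg.min_trials < 1:
        raise ConfigError("min_trials must be >= 1")
    if cfg.connectivity_channels not in ("all", "regions"):
        raise ConfigError("connectivity_channels must be 'all' or 'regions'")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run(config: dict | PipelineConfig | None = None) -> dict:
    """Run every stage on simulated (or loaded) data; return the run manifest.

    Stage order is fixed: simulate/load, preprocess+QC, time-frequency,
    connectivity, network, statistics.  Every output file is recorded in the
    manifest with a SHA-256 content hash.
    """
    cfg = validate_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": [], "files": {}}
    t_start = time.time()

    def stage(name):
        manifest["stages"].append({"name": name, "t": round(time.time() - t_start, 3)})
        logger.info("stage %s", name)

    # --- simulate -----------------------------------------------------------
    stage("simulate")
    if cfg.input != "simulate":
        raise PipelineError("only the 'simulate' input source is built in; "
                            "use the library API for recorded data")
    subjects, truth, montage = synthetic.simulate_study(cfg.study_config(), cfg.seed)
    synthetic.save_ground_truth(truth, outdir / "ground_truth.txt")

    # --- preprocessing ------------------------------------------------------
    stage("preprocess")
    qc_records = []
    cleaned: dict[tuple[str, str, str], object] = {}
    included: list[synthetic.SubjectRecording] = []
    for sub in subjects:
        counts = {}
        per_emotion = {}
        for emotion in EMOTIONS:
            es = sub.epochs[emotion]
            try:
                clean, flags = prep.preprocess(
                    es,
                    montage,
                    threshold=cfg.threshold_uv,
                    max_bad_fraction=cfg.max_bad_fraction,
                    hp_cutoff=cfg.highpass_hz,
                )
            except Exception as err:  # noqa: BLE001 - abort with stage context
                raise PipelineError(
                    f"stage preprocess failed for subject {sub.subject_id}: {err}"
                ) from err
            counts[emotion] = clean.n_trials
            per_emotion[emotion] = clean
            n_interp = [len(v) for v in flags.interpolated.values()]
            qc_records.append(
                {
                    "subject": sub.subject_id,
                    "condition": sub.condition,
                    "emotion": emotion,
                    "trials_in": es.n_trials,
                    "trials_rejected": es.n_trials - clean.n_trials,
                    "channels_interpolated_mean": float(np.mean(n_interp)) if n_interp else 0.0,
                }
            )
        if prep.qc_min_trials(counts, cfg.min_trials):
            included.append(sub)
            for emotion, clean in per_emotion.items():
                cleaned[(sub.subject_id, sub.condition, emotion)] = clean
    _write_csv(prep.qc_report(qc_records), outdir / "qc.csv")
    if not included:
        raise PipelineError("stage preprocess: no subject passed QC")

    # --- time-frequency -----------------------------------------------------
    stage("timefreq")
    tfrs = {}
    cluster_chans = sorted(
        set().union(*(montage.clusters[c] for c in (*cfg.stats_clusters, "O")))
    )
    for key, es in cleaned.items():
        tfr = timefreq.morlet_tfr(
            es,
            f_step=1.0,
            n_cycles=cfg.n_cycles,
            channels=cluster_chans,
        )
        tfr = timefreq.trim_edges(tfr, cfg.trim_ms)
        tfr = timefreq.baseline_subtract(tfr, *cfg.baseline)
        tfrs[key] = tfr
    mu_table = timefreq.mu_suppression_table(
        tfrs, montage, clusters=(*cfg.stats_clusters, "O"),
        band=cfg.band, window=cfg.analysis_window,
    )
    _write_csv(mu_table, outdir / "mu_suppression.csv")

    # --- connectivity -------------------------------------------------------
    stage("connectivity")
    conn_dir = outdir / "connectivity"
    conn_dir.mkdir(exist_ok=True)
    if cfg.connectivity_channels == "regions":
        region_chans = sorted(
            set().union(*(montage.clusters[f"R{k+1}"] for k in range(cfg.n_regions)))
        )
    else:
        region_chans = None
    matrices = {}
    for key, es in cleaned.items():
        try:
            es_csd = conn_mod.csd_transform(
                es, montage, cfg.spline_order, cfg.spline_terms, cfg.spline_reg
            )
            if region_chans is not None:
                es_csd = es_csd.select_channels(region_chans)
            cross = conn_mod.band_cross_spectrum(
                es_csd, band=cfg.band, window=cfg.connectivity_window,
                n_cycles=cfg.n_cycles,
            )
            matrices[key] = conn_mod.dwpli(cross)
        except Exception as err:  # noqa: BLE001
            raise PipelineError(
                f"stage connectivity failed for subject {key[0]}: {err}"
            ) from err
        conn_mod.save_connectivity(
            matrices[key], conn_dir / f"dwpli_{key[0]}_{key[1]}_{key[2]}.txt"
        )

    # --- network ------------------------------------------------------------
    stage("network")
    msts = {key: net_mod.mst_analysis(m, cfg.epsilon) for key, m in matrices.items()}
    metrics = net_mod.metrics_table(msts)
    _write_csv(metrics, outdir / "network_metrics.csv")

    # --- statistics ---------------------------------------------------------
    stage("stats")
    central = mu_table[mu_table["cluster"].isin(cfg.stats_clusters)]
    anova_central = stats_mod.mixed_anova(
        central, within=("cluster", "emotion")
    )
    anova_central.insert(0, "analysis", "mu_central")
    occ = mu_table[mu_table["cluster"] == "O"]
    anova_occ = stats_mod.mixed_anova(occ, within=("emotion",))
    anova_occ.insert(0, "analysis", "mu_occipital")
    net_rows = []
    for metric in ("global_efficiency", "diameter", "bc_norm"):
        tab = metrics.rename(columns={metric: "value"})
        res = stats_mod.mixed_anova(tab, within=("emotion",))
        res.insert(0, "analysis", metric)
        net_rows.append(res)
    anova_net = pd.concat(net_rows, ignore_index=True)
    # FDR across the network omnibus families (per effect, across metrics)
    adj = np.empty(len(anova_net))
    for effect in anova_net["effect"].unique():
        mask = anova_net["effect"] == effect
        adj[mask.to_numpy()] = stats_mod.fdr_bh(
            anova_net.loc[mask, "p"].to_numpy(), cfg.alpha
        )[1]
    anova_net["p_fdr"] = adj
    _write_csv(
        pd.concat([anova_central, anova_occ, anova_net], ignore_index=True),
        outdir / "anova.csv",
    )

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(outdir))] = _sha256(path)
    manifest["n_subjects_included"] = len(included)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
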