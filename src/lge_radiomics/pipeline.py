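"""End-to-end pipeline: simulate -> extract -> signature -> evaluate.

A single :class:`RunConfig` drives every stage; one master seed fans out to
per-stage seeds via ``numpy.random.SeedSequence`` so a full run is
reproducible bitwise.  Each stage writes its artifacts (feature table,
signature CSV, model-grid results, plots) plus a machine-readable JSON run
report whose content hash makes determinism checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .clinical import add_score_column
from .features import ExtractionConfig, extract_cohort_features
from .models import auc as auc_stat
from .models import evaluate_model_grid, km_logrank, youden_cutoff
from .roi import lge_burden
from .signature import (
    DEFAULT_ELBOW_FRACTION,
    DEFAULT_K_RANGE,
    DEFAULT_N_RESAMPLES,
    DEFAULT_SUBSAMPLE_FRACTION,
    build_signature,
)
from .synthetic import CohortConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "validate_config"]

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Validated pipeline configuration.

    Defaults follow the analysis conventions: 0.8 correlation-pruning
    threshold, 80% consensus subsampling, k evaluated over 2..6, 1000
    bootstrap resamples for the optimism-corrected C-statistic and 2000 for
    the NRI confidence interval.
    """

    model_config = ConfigDict(extra="forbid")

    # simulation
    n_patients: int = Field(default=270, ge=1)
    n_slices: int = Field(default=3, ge=1)
    image_size: int = Field(default=64, ge=4)
    pixel_spacing_mm: tuple[float, float] = (1.5, 1.5)
    ring_radii_mm: tuple[float, float] = (24.0, 32.0)
    roughness_range: tuple[float, float] = (0.5, 4.0)
    scar_probability: float = Field(default=0.56, ge=0.0, le=1.0)
    event_rate_target: float = Field(default=0.15, gt=0.0, lt=1.0)
    beta_texture: float = 0.7
    beta_scar: float = 1.07
    censor_horizon_years: float = Field(default=8.0, gt=0.0)
    # extraction
    n_levels: int = Field(default=32, ge=2)
    renormalize_filtered: bool = True
    # signature
    prune_threshold: float = Field(default=0.8, gt=0.0, lt=1.0)
    k_range: tuple[int, ...] = DEFAULT_K_RANGE
    n_resamples: int = Field(default=DEFAULT_N_RESAMPLES, ge=10)
    subsample_fraction: float = Field(default=DEFAULT_SUBSAMPLE_FRACTION, gt=0.0, le=1.0)
    elbow_fraction: float = Field(default=DEFAULT_ELBOW_FRACTION, gt=0.0, le=1.0)
    # evaluation
    auc_bootstrap: int = Field(default=1000, ge=100)
    nri_bootstrap: int = Field(default=2000, ge=100)
    # None: logistic outcome = any event during follow-up (default);
    # a value restricts events to those occurring within the horizon
    logistic_horizon_years: Optional[float] = Field(default=None, gt=0.0)
    km_cutoff: Optional[float] = None  # None -> Youden on the KM signature feature
    # run control
    seed: int = 0
    out_dir: str = "lge_radiomics_run"
    save_images: bool = False
    make_plots: bool = True

    @field_validator("k_range")
    @classmethod
    def _k_range_valid(cls, v):
        v = tuple(sorted(set(int(k) for k in v)))
        if len(v) < 3 or v[0] < 2:
            raise ValueError("k_range needs >= 3 values, all >= 2")
        return v

    @field_validator("ring_radii_mm")
    @classmethod
    def _radii_valid(cls, v):
        if not v[0] < v[1]:
            raise ValueError("inner ring radius must be smaller than outer")
        return v


def validate_config(raw: dict | RunConfig | None = None) -> RunConfig:
    """Fill defaults and reject invalid or unknown settings."""
    if raw is None:
        return RunConfig()
    if isinstance(raw, RunConfig):
        return raw
    return RunConfig(**raw)


def _canonical_hash(obj) -> str:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    payload = json.dumps(obj, sort_keys=True, default=_default).encode()
    return hashlib.sha256(payload).hexdigest()


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig | dict | None = None) -> dict:
    """Execute all stages and return the run report (also written to disk)."""
    config = validate_config(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    seed_sim, seed_sig, seed_eval = (int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(3))
    import lifelines
    import scipy
    import sklearn
    import statsmodels

    report: dict = {
        "version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
            "lifelines": lifelines.__version__,
        },
        "config": json.loads(config.model_dump_json()),
        "seeds": {"master": config.seed, "simulate": seed_sim, "signature": seed_sig, "evaluate": seed_eval},
        "stages": {},
    }
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s ...", name)
        timings[name] = time.perf_counter()

    def done(name, **counts):
        timings[name] = time.perf_counter() - timings[name]
        report["stages"][name] = {"seconds": round(timings[name], 2), **counts}
        logger.info("stage %s done in %.1fs %s", name, timings[name], counts)

    # ---- simulate -------------------------------------------------------
    stage("simulate")
    cohort_cfg = CohortConfig(
        n_patients=config.n_patients,
        n_slices=config.n_slices,
        image_size=config.image_size,
        pixel_spacing_mm=config.pixel_spacing_mm,
        ring_radii_mm=config.ring_radii_mm,
        roughness_range=config.roughness_range,
        scar_probability=config.scar_probability,
        event_rate_target=config.event_rate_target,
        beta_texture=config.beta_texture,
        beta_scar=config.beta_scar,
        censor_horizon_years=config.censor_horizon_years,
        seed=seed_sim,
    )
    cohort = generate_cohort(cohort_cfg)
    table = cohort.table
    if config.save_images:
        from .io import save_cohort

        save_cohort(cohort, out_dir / "cohort", images=True)
    table.to_csv(out_dir / "cohort.csv", index=False)
    done("simulate", n_patients=len(cohort.patients), n_events=int(table["event"].sum()))

    # ---- LGE quantification and clinical score --------------------------
    stage("lge_and_score")
    presence, burden = [], []
    for p in cohort.patients:
        pres, burd = lge_burden(p.slices, [p.normal_mask] * len(p.slices))
        presence.append(int(pres))
        burden.append(burd)
    table["lge_presence"] = presence
    table["lge_burden"] = burden
    table = add_score_column(table)
    done("lge_and_score", lge_prevalence=float(np.mean(presence)))

    # ---- feature extraction ---------------------------------------------
    stage("extract")
    extract_cfg = ExtractionConfig(
        n_levels=config.n_levels, renormalize_filtered=config.renormalize_filtered
    )
    features = extract_cohort_features(
        {p.patient_id: p.slices for p in cohort.patients}, extract_cfg
    )
    features.to_csv(out_dir / "features.csv")
    done("extract", n_features=features.shape[1], n_patients=features.shape[0])

    # ---- signature ------------------------------------------------------
    stage("signature")
    signature, consensus, pruned = build_signature(
        features,
        prune_threshold=config.prune_threshold,
        k_range=config.k_range,
        n_resamples=config.n_resamples,
        subsample_fraction=config.subsample_fraction,
        elbow_fraction=config.elbow_fraction,
        seed=seed_sig,
    )
    sig_df = signature.values.copy()
    sig_df.insert(0, "patient_id", sig_df.index)
    sig_df.to_csv(out_dir / "signature.csv", index=False)
    pd.DataFrame(
        {
            "k": list(consensus.cdf_area),
            "cdf_area": list(consensus.cdf_area.values()),
            "delta_area": [consensus.delta_area[k] for k in consensus.cdf_area],
        }
    ).to_csv(out_dir / "consensus_cdf.csv", index=False)
    pd.DataFrame(
        consensus.consensus[consensus.chosen_k],
        index=consensus.feature_names,
        columns=consensus.feature_names,
    ).to_csv(out_dir / "consensus_matrix.csv")
    done(
        "signature",
        n_pruned=pruned.shape[1],
        chosen_k=consensus.chosen_k,
        signature=signature.feature_names,
    )

    # ---- evaluation -----------------------------------------------------
    stage("evaluate")
    data = table.set_index("patient_id").join(signature.values, how="inner").reset_index()
    outcome = "event"
    if config.logistic_horizon_years is not None:
        data["event_within_horizon"] = (
            (data["event"] == 1)
            & (data["time_years"] <= config.logistic_horizon_years)
        ).astype(int)
        outcome = "event_within_horizon"
    auc_table, comparisons, evals = evaluate_model_grid(
        data,
        signature.feature_names,
        outcome=outcome,
        n_boot=config.auc_bootstrap,
        nri_boot=config.nri_bootstrap,
        seed=seed_eval,
    )
    auc_table.to_csv(out_dir / "model_grid_auc.csv", index=False)
    comparisons.to_csv(out_dir / "model_comparisons.csv", index=False)

    # KM grouping feature: the signature member with the strongest univariate
    # discrimination of the endpoint (the analog of picking the best
    # single-feature model before reading the Youden cutoff)
    y_arr = data["event"].to_numpy()
    km_feature = max(
        signature.feature_names,
        key=lambda f: abs(auc_stat(data[f].to_numpy(dtype=float), y_arr) - 0.5),
    )
    feat_vals = data[km_feature].to_numpy(dtype=float)
    cutoff = (
        config.km_cutoff
        if config.km_cutoff is not None
        else youden_cutoff(feat_vals, data["event"].to_numpy())
    )
    groups = np.where(feat_vals > cutoff, "high", "low")
    if len(np.unique(groups)) == 2:
        _, km_chi2, km_p = km_logrank(
            data["time_years"].to_numpy(), data["event"].to_numpy(), groups
        )
    else:
        km_chi2, km_p = float("nan"), float("nan")
    done("evaluate", n_models=len(evals), km_cutoff=float(cutoff), km_logrank_p=km_p)

    results = {
        "event_rate": float(table["event"].mean()),
        "lge_prevalence": float(np.mean(presence)),
        "n_features": int(features.shape[1]),
        "n_features_pruned": int(pruned.shape[1]),
        "chosen_k": int(consensus.chosen_k),
        "signature_features": signature.feature_names,
        "model_grid": auc_table.to_dict(orient="records"),
        "comparisons": comparisons.to_dict(orient="records"),
        "km_feature": km_feature,
        "km_cutoff": float(cutoff),
        "km_logrank_chi2": km_chi2,
        "km_logrank_p": km_p,
    }
    report["results"] = _round_floats(results)
    report["results_hash"] = _canonical_hash(report["results"])

    if config.make_plots:
        try:
            _make_plots(out_dir, data, consensus, evals, km_feature, cutoff)
        except Exception as exc:  # plots are best-effort
            logger.warning("plotting failed: %s", exc)

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _make_plots(out_dir, data, consensus, evals, km_feature, cutoff):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    y = data["event"].to_numpy()

    fig, ax = plt.subplots(figsize=(5, 5))
    for name in ("clinical_lge_presence", "clinical_lge_presence_radiomics"):
        fpr, tpr, _ = roc_curve(y, evals[name].risks)
        ax.plot(fpr, tpr, label=f"{name} (AUC {evals[name].apparent_auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    fig.savefig(out_dir / "roc.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ks = list(consensus.cdf_area)
    ax.plot(ks, [consensus.cdf_area[k] for k in ks], "o-", label="A(k)")
    ax.plot(ks, [consensus.delta_area[k] for k in ks], "s--", label="relative change")
    ax.axvline(consensus.chosen_k, color="r", lw=0.8)
    ax.set_xlabel("k")
    ax.legend()
    fig.savefig(out_dir / "consensus_cdf.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    from .models import km_logrank as _km

    feat = data[km_feature].to_numpy(dtype=float)
    groups = np.where(feat > cutoff, "high", "low")
    if len(np.unique(groups)) == 2:
        fitters, _, p = _km(data["time_years"].to_numpy(), y, groups)
        fig, ax = plt.subplots(figsize=(5, 4))
        for lab, kmf in fitters.items():
            kmf.plot_survival_function(ax=ax)
        ax.set_title(f"{km_feature} > {cutoff:.3g} (log-rank p = {p:.3g})", fontsize=8)
        ax.set_xlabel("years")
        ax.set_ylabel("arrhythmia-free survival")
        fig.savefig(out_dir / "km.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
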