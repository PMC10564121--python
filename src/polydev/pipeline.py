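"""End-to-end orchestration: score -> simulate -> classify -> enrich -> report.

A single :class:`PipelineConfig` (YAML-serialisable) drives a run on either
real tabular inputs (weights + dosages + covariates) or an embedded
synthetic study. All randomness flows from one root seed expanded into
per-stage child seeds, which are logged in the manifest; two runs with the
same config and seed produce byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify as dc
from .cohort import (
    adjust_and_standardize,
    build_pairs,
    compute_polygenic_score,
    read_covariates,
    read_dosages,
    read_weights,
    standardize,
)
from .enrich import ContingencyTable, binary_enrichment
from .errors import ConfigError, DataError
from .simulate import PlantSpec, SimConfig, generate_synthetic_study, simulate_null_cohort, simulate_rank_null

logger = logging.getLogger(__name__)

METHODS = ("mahalanobis", "residual", "grs_rank", "centile")


@dataclass
class PipelineConfig:
    """Everything one analysis run needs.

    Exactly one of ``inputs`` (paths to real tables) or ``sim`` (embedded
    simulation) must be present.
    """

    seed: int = 0
    outdir: str = "polydev_out"
    inputs: Optional[dict] = None
    sim: Optional[SimConfig] = None
    plant: PlantSpec = field(default_factory=PlantSpec)
    methods: Sequence[str] = METHODS
    mahalanobis_alphas: Sequence = (1e-3, "0.05/n")
    residual_ks: Sequence[float] = (2.0, 3.0)
    centile_ks: Sequence[float] = (1.5, 3.0)
    centile_bins: int = 100
    rank_alphas: Sequence[float] = (1e-3,)
    direction_rule: str = "phenotype"
    residual_direction: str = "pheno_on_score"
    sex_stratified: bool = False
    plots: bool = False

    def __post_init__(self):
        if (self.inputs is None) == (self.sim is None):
            raise ConfigError("exactly one of 'inputs' and 'sim' must be configured")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ConfigError(f"unsupported method(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        if "plant" in raw and raw["plant"] is not None:
            plant = dict(raw["plant"])
            if plant.get("sexed") is not None:
                plant["sexed"] = tuple(plant["sexed"])
            raw["plant"] = PlantSpec(**plant)
        return cls(**raw)

    def to_dict(self) -> dict:
        out = asdict(self)
        for key in ("methods", "mahalanobis_alphas", "residual_ks", "centile_ks", "rank_alphas"):
            out[key] = list(out[key])
        return out


def _child_seeds(seed: int, k: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(k)]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_real_inputs(config: PipelineConfig):
    """Join weights/dosages/covariates and build the standardized pair table."""
    paths = config.inputs
    for key in ("weights", "dosages", "covariates", "phenotype_col"):
        if key not in paths:
            raise ConfigError(f"inputs block is missing {key!r}")
    weights = read_weights(paths["weights"])
    dosages = read_dosages(paths["dosages"])
    cov = read_covariates(paths["covariates"])

    keep = np.intersect1d(dosages.individual_ids, cov["individual_id"].to_numpy())
    dropped = len(set(dosages.individual_ids) | set(cov["individual_id"])) - len(keep)
    if dropped:
        logger.info("dropped %d individuals absent from one of the input tables", dropped)
    didx = {iid: i for i, iid in enumerate(dosages.individual_ids)}
    rows = [didx[i] for i in keep]
    from .cohort import DosageMatrix

    dosages = DosageMatrix(
        individual_ids=keep, variant_ids=dosages.variant_ids, dosage=dosages.dosage[rows]
    )
    cov = cov.set_index("individual_id").loc[keep].reset_index()

    raw_score = compute_polygenic_score(dosages, weights)
    score_covs = paths.get("score_covariates", [c for c in cov.columns if c.startswith("pc")])
    ps_z = adjust_and_standardize(raw_score, cov, score_covs) if score_covs else standardize(raw_score)
    pheno_covs = paths.get("covariate_names", [])
    transform = paths.get("transform", "none")
    pheno = cov[paths["phenotype_col"]].to_numpy(dtype=float)
    pheno_z = adjust_and_standardize(pheno, cov, pheno_covs, transform=transform)
    pairs = build_pairs(keep, ps_z, pheno_z)
    sex = cov["sex"].to_numpy() if "sex" in cov.columns else None
    checksums = {k: _sha256(paths[k]) for k in ("weights", "dosages", "covariates")}
    return pairs, None, sex, checksums


def _restandardize(pairs: pd.DataFrame) -> pd.DataFrame:
    out = pairs.copy()
    out["ps_z"] = standardize(out["ps_z"].to_numpy())
    out["pheno_z"] = standardize(out["pheno_z"].to_numpy())
    return out


def _classify_stratum(
    pairs: pd.DataFrame, config: PipelineConfig, seeds: dict, suffix: str = ""
) -> list[dc.CallSet]:
    """Run every configured method/threshold on one (sub)cohort."""
    n = len(pairs)
    callsets: list[dc.CallSet] = []
    kw = dict(residual_direction=config.residual_direction)
    # calibration simulations match the variance explained observed in the
    # analysed cohort, as in the source design
    r2_obs = float(
        np.clip(np.corrcoef(pairs["ps_z"], pairs["pheno_z"])[0, 1] ** 2, 1e-4, 0.99)
    )
    if "mahalanobis" in config.methods:
        null_cfg = _calibration_config(config, n, seeds["maha_null"], r2_obs)
        model = dc.fit_mahalanobis(simulate_null_cohort(null_cfg).pairs)
        for alpha in config.mahalanobis_alphas:
            if alpha == "0.05/n":
                a, label = 0.05 / n, "P<0.05/n"
            else:
                a, label = float(alpha), f"P<{float(alpha):g}"
            callsets.append(
                dc.classify_mahalanobis(
                    pairs, model, alpha=a, threshold_label=label + suffix,
                    direction_rule=config.direction_rule, **kw,
                )
            )
    if "residual" in config.methods:
        for k in config.residual_ks:
            callsets.append(
                dc.classify_residual(
                    pairs, k=k, threshold_label=f"|z|>{k:g}" + suffix,
                    direction_rule=config.direction_rule, **kw,
                )
            )
    if "grs_rank" in config.methods:
        null_cfg = _calibration_config(config, n, seeds["rank_null"], r2_obs, fast=True)
        store = simulate_rank_null(null_cfg)
        for alpha in config.rank_alphas:
            callsets.append(
                dc.classify_grs_rank(
                    pairs, store, alpha=float(alpha), tie_seed=seeds["ties"],
                    threshold_label=f"P<{float(alpha):g}" + suffix, **kw,
                )
            )
    if "centile" in config.methods:
        for k in config.centile_ks:
            callsets.append(
                dc.classify_centile(
                    pairs, k_iqr=k, bins=config.centile_bins,
                    threshold_label=f"{k:g}xIQR" + suffix, **kw,
                )
            )
    return callsets


def _calibration_config(
    config: PipelineConfig, n: int, seed: int, r2: float, fast: bool = False
) -> SimConfig:
    base = config.sim if config.sim is not None else SimConfig(n=n, seed=seed)
    return SimConfig(
        n=n, m=base.m, target_r2=r2, seed=seed, B=base.B,
        maf=base.maf if isinstance(base.maf, tuple) else np.asarray(base.maf),
        genotype_level=base.genotype_level and not fast,
    )


def report_counts(callsets: Sequence[dc.CallSet], n: int) -> pd.DataFrame:
    """Deviator counts and cohort percentages per method/threshold."""
    rows = []
    for c in callsets:
        k = c.counts()
        rows.append(
            {
                "method": c.method,
                "threshold_label": c.threshold_label,
                "n_low": k["deviator_low"],
                "n_high": k["deviator_high"],
                "n_aligned": k["aligned"],
                "n_intermediate": k["intermediate"],
                "pct_low": round(100.0 * k["deviator_low"] / n, 2),
                "pct_high": round(100.0 * k["deviator_high"] / n, 2),
            }
        )
    return pd.DataFrame(rows)


def _truth_enrichment(
    callsets: Sequence[dc.CallSet], labels: pd.DataFrame
) -> pd.DataFrame:
    """Planted-carrier enrichment in each deviator group vs the aligned group."""
    exposed = set(labels.loc[labels["truth"] != "null", "individual_id"])
    rows = []
    for c in callsets:
        aligned = c.ids("aligned")
        for direction in ("deviator_low", "deviator_high"):
            dev = c.ids(direction)
            if not dev or not aligned:
                continue
            t = ContingencyTable(
                a=len(dev & exposed), b=len(dev - exposed),
                c=len(aligned & exposed), d=len(aligned - exposed),
            )
            res = binary_enrichment(t, method="fisher_exact")
            row = {"outcome": "planted_carrier", "method": c.method,
                   "threshold_label": c.threshold_label, "group": direction}
            row.update(res.to_row())
            rows.append(row)
    return pd.DataFrame(rows)


def _plot_panels(pairs: pd.DataFrame, callsets, outdir: Path) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort and never fails the run
        logger.warning("matplotlib unavailable; skipping plots")
        return
    k = len(callsets)
    ncol = min(4, k)
    nrow = (k + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 4 * nrow), squeeze=False)
    for ax, c in zip(axes.ravel(), callsets):
        dev = c.table["status"].isin(["deviator_low", "deviator_high"]).to_numpy()
        ax.scatter(pairs["ps_z"][~dev], pairs["pheno_z"][~dev], s=2, c="k", alpha=0.3)
        ax.scatter(pairs["ps_z"][dev], pairs["pheno_z"][dev], s=6, c="r")
        ax.set_title(c.label, fontsize=9)
        ax.set_xlabel("polygenic score (z)")
        ax.set_ylabel("phenotype (z)")
    for ax in axes.ravel()[k:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(outdir / "panels.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of output paths and tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("polydev")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        seed_names = ("cohort", "maha_null", "rank_null", "ties")
        seeds = dict(zip(seed_names, _child_seeds(config.seed, len(seed_names))))
        logger.info("child seeds: %s", seeds)

        labels = None
        checksums: dict = {}
        if config.sim is not None:
            sim_cfg = SimConfig(**{**asdict_sim(config.sim), "seed": seeds["cohort"]})
            cohort, labels = generate_synthetic_study(sim_cfg, config.plant)
            pairs, sex = cohort.pairs, cohort.sex
            logger.info("synthetic cohort n=%d realized_r2=%.4f", len(pairs), cohort.realized_r2)
        else:
            pairs, labels, sex, checksums = _load_real_inputs(config)

        strata = {"": pairs}
        if config.sex_stratified:
            if sex is None:
                raise ConfigError("sex_stratified requested but no sex information available")
            strata = {
                f"|{s}": _restandardize(pairs[np.asarray(sex) == s].reset_index(drop=True))
                for s in pd.unique(np.asarray(sex))
            }

        callsets: list[dc.CallSet] = []
        for suffix, sub in strata.items():
            callsets.extend(_classify_stratum(sub, config, seeds, suffix=suffix))

        for c in callsets:
            safe = c.label.replace("|", "_").replace("<", "").replace("/", "-").replace(">", "")
            c.write(outdir / f"calls_{safe}.tsv")

        counts = report_counts(callsets, len(pairs))
        counts.to_csv(outdir / "counts.tsv", sep="\t", index=False, float_format="%.8g")

        overlap_paths = {}
        if not config.sex_stratified and len(callsets) > 1:
            overlap = dc.method_overlap(callsets)
            for direction, sub in overlap.groupby("direction"):
                path = outdir / f"overlap_{direction}.tsv"
                sub.to_csv(path, sep="\t", index=False, float_format="%.8g")
                overlap_paths[direction] = path

        enrichment = pd.DataFrame()
        if labels is not None:
            enrichment = _truth_enrichment(callsets, labels)
            enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.8g")
            labels.to_csv(outdir / "truth_labels.tsv", sep="\t", index=False)

        pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False, float_format="%.10g")

        manifest = {
            "seed": config.seed,
            "child_seeds": seeds,
            "config": config.to_dict(),
            "input_checksums": checksums,
            "n": len(pairs),
            "callsets": [c.label for c in callsets],
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

        if config.plots:
            _plot_panels(pairs, callsets, outdir)

        return {
            "pairs": pairs,
            "callsets": callsets,
            "counts": counts,
            "enrichment": enrichment,
            "outdir": outdir,
            "manifest": manifest,
        }
    finally:
        root.removeHandler(handler)
        handler.close()


def asdict_sim(sim: SimConfig) -> dict:
    out = asdict(sim)
    if isinstance(out["maf"], tuple):
        out["maf"] = tuple(out["maf"])
    return out


def demo_config(outdir: str, seed: int = 0) -> PipelineConfig:
    """The packaged demonstration study: a 10,000-person synthetic cohort
    with 60 planted deviators, all four methods at two thresholds each."""
    return PipelineConfig(
        seed=seed,
        outdir=outdir,
        sim=SimConfig(n=10_000, m=200, target_r2=0.316, B=2_000, genotype_level=False),
        plant=PlantSpec(n_low=30, n_high=30, shift_sd=4.0),
        methods=METHODS,
        mahalanobis_alphas=(1e-3, "0.05/n"),
        residual_ks=(2.0, 3.0),
        centile_ks=(1.5, 3.0),
        rank_alphas=(1e-3, 5e-4),
        centile_bins=100,
    )
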