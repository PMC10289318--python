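"""End-to-end orchestration of the areal mortality analysis.

The workflow mirrors a classical ecological spatial study: load (or
simulate) the municipality map -> queen contiguity weights -> crude and
empirical-Bayes-smoothed mortality rates -> global Moran's I -> LISA
cluster map -> 2SFCA accessibility -> OLS with condition-number check
-> |t| > 1.96 variable screening -> GWR -> model-comparison report.

Stages communicate through files in the output directory so each stage
can be re-run individually from cached intermediates; re-running a
downstream stage never mutates upstream artifacts.  All data artifacts
are deterministic under a fixed seed; wall-clock timings go only to
``run.log``, which is not part of the reproducible artifact set.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .access import two_step_fca
from .io import (
    read_area_layer,
    read_providers,
    read_weights,
    write_area_layer,
    write_providers,
    write_weights,
)
from .moran import LocalMoran, Moran
from .rates import eb_smooth_spatial, exam_rate, mortality_rate
from .regression import GWR, SpatialOLS, compare_models, screen_variables
from .synthetic import SyntheticConfig, generate_dataset, write_truth
from .weights import queen_weights

__all__ = ["AnalysisConfig", "PipelineConfig", "run_pipeline", "STAGES"]

DEFAULT_COVARIATES = ["tpr", "exam_rate", "access", "ipdm"]


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters shared by all stages."""

    d0: float = 60_000.0              # 2SFCA catchment radius, meters
    n_perm: int = 999                 # permutations for Moran / LISA
    alpha: float = 0.05               # LISA significance level
    screen_threshold: float = 1.96    # |t| cutoff carrying covariates to GWR
    kernel: str = "adaptive_bisquare"
    bandwidth: object = "AICc"
    use_smoothed_outcome: bool = True
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    period: float = 5.0               # person-year multiplier for rates
    seed: int = 0                     # inference seed (permutations)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")


@dataclass
class PipelineConfig:
    """Exactly one of ``synthetic`` (generator parameters) or ``inputs``
    (paths to an area GeoJSON and a provider CSV/GeoJSON) must be set."""

    output_dir: str = "arealepi_run"
    synthetic: SyntheticConfig | None = None
    inputs: dict | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of a synthetic block or real input paths must be given"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        syn = d.get("synthetic")
        if syn is not None:
            syn = SyntheticConfig(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in syn.items()})
        ana = AnalysisConfig(**d.get("analysis", {}))
        return cls(output_dir=d.get("output_dir", "arealepi_run"),
                   synthetic=syn, inputs=d.get("inputs"), analysis=ana)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "output_dir": self.output_dir,
            "synthetic": self.synthetic.to_dict() if self.synthetic else None,
            "inputs": self.inputs,
            "analysis": dataclasses.asdict(self.analysis),
        }


def _out(cfg: PipelineConfig) -> Path:
    p = Path(cfg.output_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _load_areas(cfg: PipelineConfig) -> pd.DataFrame:
    return read_area_layer(_out(cfg) / "areas.geojson")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    if cfg.synthetic is not None:
        ds = generate_dataset(cfg.synthetic)
        write_area_layer(ds.areas, out / "areas.geojson")
        write_providers(ds.providers, out / "providers.csv")
        write_truth(ds.truth, ds.config, out / "truth.json")
        n = len(ds.areas)
    else:
        areas = read_area_layer(
            cfg.inputs["area_path"],
            id_field=cfg.inputs.get("id_field", "unit_id"),
            crs_policy=cfg.inputs.get("crs_policy", "require_metric"),
        )
        write_area_layer(areas, out / "areas.geojson")
        providers = read_providers(cfg.inputs["providers_path"])
        write_providers(providers, out / "providers.csv")
        n = len(areas)
    return {"n_units": n}


def stage_weights(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    areas = _load_areas(cfg)
    w = queen_weights(areas, mode="binary")
    write_weights(w, out / "weights.gal")
    return {"n_islands": len(w.islands), "mean_degree": float(w.degrees.mean())}


def stage_rates(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    areas = _load_areas(cfg)
    wb = read_weights(out / "weights.gal", mode="binary")
    crude = mortality_rate(areas, period=cfg.analysis.period)
    smoothed = eb_smooth_spatial(crude, wb)
    smoothed.to_csv(out / "rates.csv", index=False)
    return {
        "mean_crude_rate": float(crude["crude_rate"].mean()),
        "mean_smoothed_rate": float(smoothed["smoothed_rate"].mean()),
    }


def _outcome(cfg: PipelineConfig, rates: pd.DataFrame) -> np.ndarray:
    col = "smoothed_rate" if cfg.analysis.use_smoothed_outcome else "crude_rate"
    return rates[col].to_numpy(dtype=float)


def stage_moran(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    rates = pd.read_csv(out / "rates.csv")
    w = read_weights(out / "weights.gal", mode="row_standardized")
    m = Moran(weights=w, permutations=cfg.analysis.n_perm,
              seed=cfg.analysis.seed).fit(_outcome(cfg, rates))
    res = {
        "I": m.I_,
        "expected_I": m.expected_I_,
        "pseudo_p": m.p_sim_,
        "z_sim": m.z_sim_,
        "n_perm": cfg.analysis.n_perm,
        "seed": cfg.analysis.seed,
        "n": m.n_,
    }
    with open(out / "moran.json", "w") as fh:
        json.dump(res, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return res


def stage_lisa(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    rates = pd.read_csv(out / "rates.csv")
    areas = _load_areas(cfg)
    w = read_weights(out / "weights.gal", mode="row_standardized")
    lm = LocalMoran(weights=w, permutations=cfg.analysis.n_perm,
                    alpha=cfg.analysis.alpha, seed=cfg.analysis.seed
                    ).fit(_outcome(cfg, rates))
    tab = lm.to_frame(ids=rates["unit_id"])
    tab.to_csv(out / "lisa.csv", index=False)
    clusters = areas[["unit_id", "geometry"]].copy()
    clusters["label"] = lm.labels_
    clusters["quadrant"] = lm.quadrant_
    write_area_layer(clusters, out / "clusters.geojson")
    counts = pd.Series(lm.labels_).value_counts().to_dict()
    return {
        "n_hot_spots": int(counts.get("hot_spot", 0)),
        "n_cold_spots": int(counts.get("cold_spot", 0)),
        "n_outliers": int(counts.get("outlier_HL", 0) + counts.get("outlier_LH", 0)),
    }


def stage_access(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    areas = _load_areas(cfg)
    providers = read_providers(out / "providers.csv")
    a = two_step_fca(areas, providers, d0=cfg.analysis.d0)
    pd.DataFrame({"unit_id": areas["unit_id"], "access": a * 100_000.0}).to_csv(
        out / "access.csv", index=False
    )
    return {"mean_access_per_100k": float(a.mean() * 100_000.0),
            "n_unserved": int((a == 0).sum())}


def stage_regress(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    areas = _load_areas(cfg)
    rates = pd.read_csv(out / "rates.csv")
    access = pd.read_csv(out / "access.csv")
    w = read_weights(out / "weights.gal", mode="row_standardized")

    X = pd.DataFrame(index=areas.index)
    for name in cfg.analysis.covariates:
        if name == "exam_rate":
            X[name] = exam_rate(areas)
        elif name == "access":
            X[name] = access["access"].to_numpy()
        else:
            X[name] = areas[name].to_numpy(dtype=float)
    y = _outcome(cfg, rates)

    ols = SpatialOLS(weights=w, permutations=cfg.analysis.n_perm,
                     seed=cfg.analysis.seed).fit(X, y)
    selected = screen_variables(ols, threshold=cfg.analysis.screen_threshold)
    if not selected:
        selected = list(X.columns)  # nothing passes: keep the full design, flagged
    coords = np.array([[g.centroid.x, g.centroid.y] for g in areas["geometry"]])
    gwr = GWR(kernel=cfg.analysis.kernel, bandwidth=cfg.analysis.bandwidth,
              weights=w, permutations=cfg.analysis.n_perm,
              seed=cfg.analysis.seed).fit(X[selected], y, coords)
    # comparison requires identical designs: refit OLS on the screened set
    ols_sel = (ols if selected == list(X.columns)
               else SpatialOLS(weights=w, permutations=cfg.analysis.n_perm,
                               seed=cfg.analysis.seed).fit(X[selected], y))
    report = compare_models(ols_sel, gwr)

    report.coefficients.to_csv(out / "model_report_coefficients.csv",
                               index_label="Variable")
    report.summary.to_csv(out / "model_report_summary.csv", index_label="Criterion")
    payload = report.to_json_dict()
    payload.update(
        {
            "screened_covariates": selected,
            "screen_threshold": cfg.analysis.screen_threshold,
            "condition_number": ols.cond_number_,
            "gwr_bandwidth": gwr.bandwidth_,
            "gwr_effective_params": gwr.tr_S_,
        }
    )
    with open(out / "model_report.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")

    surf = areas[["unit_id", "geometry"]].copy()
    for j, name in enumerate(gwr.coef_names_):
        surf[f"coef_{name}"] = gwr.local_coef_[:, j]
        surf[f"t_{name}"] = gwr.local_tvalues_[:, j]
        # sign classes where the local effect is significant (|t| > 1.96)
        sig = np.abs(gwr.local_tvalues_[:, j]) > 1.96
        surf[f"sign_{name}"] = np.where(
            sig, np.where(gwr.local_coef_[:, j] > 0, "positive", "negative"), "ns"
        )
    write_area_layer(surf, out / "coef_surface.geojson")
    return {
        "selected": selected,
        "condition_number": ols.cond_number_,
        "ols_aic": ols_sel.aic_,
        "gwr_aicc": gwr.aicc_,
        "ols_adj_r2": ols_sel.adj_r2_,
        "gwr_adj_r2": gwr.adj_r2_,
        "ols_residual_moran_I": ols_sel.residual_moran_.I_,
        "gwr_residual_moran_I": gwr.residual_moran_.I_,
        "verdict": report.verdict,
    }


STAGES = {
    "simulate": stage_simulate,
    "weights": stage_weights,
    "rates": stage_rates,
    "moran": stage_moran,
    "lisa": stage_lisa,
    "access": stage_access,
    "regress": stage_regress,
}

_ORDER = ["simulate", "weights", "rates", "moran", "lisa", "access", "regress"]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order; returns the merged stage summaries.

    Writes a parameter manifest (``manifest.json``, deterministic) and a
    human-readable ``run.log`` with timings and the headline numbers.
    """
    out = _out(cfg)
    results: dict = {}
    log_lines = [f"arealepi {__version__} pipeline run"]
    for name in _ORDER:
        t0 = time.perf_counter()
        try:
            res = STAGES[name](cfg)
        except Exception as exc:
            (out / "run.log").write_text(
                "\n".join(log_lines + [f"stage {name} FAILED: {exc}",
                                       "partial outputs are incomplete"]) + "\n"
            )
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        results[name] = res
        log_lines.append(f"stage {name}: {dt:.2f}s {res}")

    manifest = {"package_version": __version__, "config": cfg.to_dict()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    m, l = results["moran"], results["lisa"]
    log_lines.append(
        f"global Moran's I = {m['I']:.3f} (pseudo p = {m['pseudo_p']:.3f}); "
        f"{l['n_hot_spots']} high-high (hot spot) and "
        f"{l['n_cold_spots']} low-low (cold spot) units"
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return results
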