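"""Design-space sweep over the deposition simulator, tree organisation of
the results and selection of the porosity / pore-uniformity optimum.

A design is one combination of fiber-population and deposition
parameters; each design is simulated with several replicate seeds, the
top view is analysed like a micrograph, and the resulting table is
organised with regression and decision (classification) trees.  A design
is *suitable* when its pore-area P5/P95 fall inside a physical window
(default 0.02-120 µm²); among suitable designs the optimum is the one
with the most uniform pores (minimal pore-area CV).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .deposition_sim import SimConfig, simulate_structure
from .population import FiberPopulationSpec
from .structure_metrics import bulk_porosity, compute_metrics, render_top_view
from .trees import TreeModel, fit_classification_tree, fit_regression_tree

logger = logging.getLogger(__name__)

SAMPLING_SCHEMES = ("full-factorial", "latin-hypercube", "uniform-random")
_FACTORIAL_CAP = 100_000

#: metric columns every successful results row carries
METRIC_COLUMNS = [
    "surface_porosity",
    "bulk_porosity",
    "pore_count",
    "pore_area_p5_um2",
    "pore_area_p95_um2",
    "pore_area_cv",
    "pore_area_mean_um2",
    "fiber_width_mean_um",
    "fiber_width_p5_um",
    "fiber_width_p95_um",
    "n_fibers",
]


class DesignError(ValueError):
    pass


@dataclass
class ParamSpec:
    """One swept parameter: continuous range, integer range or explicit
    levels.  ``log`` samples continuous ranges uniformly in log space."""

    kind: str  # "continuous" | "integer" | "levels"
    range: tuple[float, float] | None = None
    levels: list | None = None
    log: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "integer", "levels"):
            raise DesignError(f"unknown parameter kind {self.kind!r}")
        if self.kind == "levels":
            if not self.levels:
                raise DesignError("levels parameter needs a non-empty list")
        else:
            if self.range is None or not self.range[0] <= self.range[1]:
                raise DesignError(f"bad range {self.range}")

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        """Map stratified unit-interval samples onto the parameter."""
        if self.kind == "levels":
            idx = np.minimum((u * len(self.levels)).astype(int), len(self.levels) - 1)
            return np.asarray(self.levels, dtype=object)[idx]
        lo, hi = self.range
        if self.log:
            vals = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
        else:
            vals = lo + u * (hi - lo)
        if self.kind == "integer":
            vals = np.floor(lo + u * (hi - lo + 1)).clip(lo, hi).astype(int)
        return vals

    def grid(self) -> list:
        if self.kind == "levels":
            return list(self.levels)
        raise DesignError(
            "full-factorial sampling requires explicit levels for every parameter"
        )


@dataclass
class DesignSpace:
    params: dict[str, ParamSpec]
    scheme: str = "latin-hypercube"
    n_designs: int = 200
    seeds_per_design: int = 5

    def __post_init__(self) -> None:
        if self.scheme not in SAMPLING_SCHEMES:
            raise DesignError(f"scheme {self.scheme!r} not in {SAMPLING_SCHEMES}")
        if self.n_designs < 1:
            raise DesignError("n_designs must be >= 1")
        if self.seeds_per_design < 1:
            raise DesignError("seeds_per_design must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpace":
        params = {}
        for name, p in d["params"].items():
            p = dict(p)
            if "range" in p and p["range"] is not None:
                p["range"] = tuple(p["range"])
            params[name] = ParamSpec(**p)
        return cls(
            params=params,
            scheme=d.get("scheme", "latin-hypercube"),
            n_designs=int(d.get("n_designs", 200)),
            seeds_per_design=int(d.get("seeds_per_design", 5)),
        )


@dataclass
class SuitabilityCriteria:
    pore_window_um2: tuple[float, float] = (0.02, 120.0)
    porosity_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.pore_window_um2
        if not lo < hi:
            raise DesignError(f"pore window needs lo < hi, got ({lo}, {hi})")
        if self.porosity_band is not None and not (
            self.porosity_band[0] < self.porosity_band[1]
        ):
            raise DesignError(f"bad porosity band {self.porosity_band}")


@dataclass
class OptimumReport:
    design_index: int
    parameters: dict
    mean_surface_porosity: float
    porosity_sd: float
    pore_area_p5_um2: float
    pore_area_p95_um2: float
    pore_area_cv: float
    n_replicates: int
    n_suitable_designs: int
    criteria: dict

    def to_dict(self) -> dict:
        return {
            "design_index": self.design_index,
            "parameters": self.parameters,
            "mean_surface_porosity": self.mean_surface_porosity,
            "porosity_sd": self.porosity_sd,
            "pore_area_p5_um2": self.pore_area_p5_um2,
            "pore_area_p95_um2": self.pore_area_p95_um2,
            "pore_area_cv": self.pore_area_cv,
            "n_replicates": self.n_replicates,
            "n_suitable_designs": self.n_suitable_designs,
            "criteria": self.criteria,
        }

    def to_markdown(self) -> str:
        lines = [
            "# Selected optimum",
            "",
            f"- design index: {self.design_index}",
            f"- mean surface porosity: {self.mean_surface_porosity:.3f} "
            f"(SD {self.porosity_sd:.3f}, {self.n_replicates} replicates)",
            f"- pore area P5/P95: {self.pore_area_p5_um2:.3g} / "
            f"{self.pore_area_p95_um2:.3g} um^2",
            f"- pore area CV: {self.pore_area_cv:.3f}",
            f"- suitable designs: {self.n_suitable_designs}",
            "",
            "## Parameters",
            "",
        ]
        lines += [f"- {k}: {v}" for k, v in self.parameters.items()]
        return "\n".join(lines)


def derive_seed(master_seed: int, stage: str, *indices: int) -> int:
    """Stable per-stage seed: blake2 hash of (master seed, stage, indices)."""
    key = f"{master_seed}:{stage}:" + ":".join(str(i) for i in indices)
    return int.from_bytes(
        hashlib.blake2b(key.encode(), digest_size=8).digest(), "big"
    ) % (2**63)


def generate_design(space: DesignSpace, seed: int) -> pd.DataFrame:
    """Parameter table per the space's sampling scheme; deterministic.

    Latin-hypercube marginals are stratified: for each parameter the n
    samples occupy the n equal-probability strata exactly once.
    """
    names = list(space.params)
    if space.scheme == "full-factorial":
        grids = [space.params[n].grid() for n in names]
        n_cells = int(np.prod([len(g) for g in grids]))
        if n_cells > _FACTORIAL_CAP:
            raise DesignError(
                f"full factorial would need {n_cells} cells (> {_FACTORIAL_CAP}); "
                "use latin-hypercube or uniform-random sampling"
            )
        mesh = np.meshgrid(*[np.arange(len(g)) for g in grids], indexing="ij")
        rows = {
            name: np.asarray(grid, dtype=object)[m.ravel()]
            for name, grid, m in zip(names, grids, mesh)
        }
        df = pd.DataFrame(rows)
    else:
        rng = np.random.default_rng(seed)
        n = space.n_designs
        cols = {}
        for name in names:
            if space.scheme == "latin-hypercube":
                u = (rng.permutation(n) + rng.random(n)) / n
            else:
                u = rng.random(n)
            cols[name] = space.params[name].from_unit(u)
        df = pd.DataFrame(cols)
    df.insert(0, "design_index", np.arange(len(df)))
    return df


# design-table columns consumed by the simulator, with SimConfig targets
_POPULATION_FIELDS = {
    "width_min_um",
    "width_max_um",
    "width_law",
    "aspect_ratio",
    "wall_thickness_um",
    "lumen_um",
    "flexibility",
    "mixture_weight",
}
_CONFIG_FIELDS = {"target_layers", "resolution_um_per_voxel"}


def config_for_design(base: SimConfig, row: dict) -> SimConfig:
    """Override the base simulation config with one design row."""
    pop = base.population.to_dict()
    cfg = base.to_dict()
    wlo, whi = pop["width_range_um"]
    for key, val in row.items():
        if key == "width_min_um":
            wlo = float(val)
        elif key == "width_max_um":
            whi = float(val)
        elif key in _POPULATION_FIELDS:
            pop[key] = val if key == "width_law" else float(val)
        elif key in _CONFIG_FIELDS:
            cfg[key] = float(val)
    pop["width_range_um"] = (wlo, whi)
    if "flexibility" in pop:
        pop["flexibility"] = int(round(float(pop["flexibility"])))
    cfg["population"] = pop
    return SimConfig.from_dict(cfg)


def run_one(
    base: SimConfig, row: dict, seed: int
) -> dict:
    """Simulate one (design, replicate) and measure its top view."""
    cfg = config_for_design(base, row)
    cfg.seed = seed
    st = simulate_structure(cfg)
    top = render_top_view(st, cfg.top_view_depth_voxels)
    m = compute_metrics(top, structure=st)
    ps = m.pore_stats
    fw = m.fiber_width_stats
    return {
        "surface_porosity": m.surface_porosity,
        "bulk_porosity": m.bulk_porosity,
        "pore_count": ps.count if ps else 0,
        "pore_area_p5_um2": ps.p5_um2 if ps else np.nan,
        "pore_area_p95_um2": ps.p95_um2 if ps else np.nan,
        "pore_area_cv": ps.cv if ps else np.nan,
        "pore_area_mean_um2": ps.mean_um2 if ps else np.nan,
        "fiber_width_mean_um": fw.mean_um if fw else np.nan,
        "fiber_width_p5_um": fw.p5_um if fw else np.nan,
        "fiber_width_p95_um": fw.p95_um if fw else np.nan,
        "n_fibers": st.placed_fiber_count,
    }


def run_batch(
    design: pd.DataFrame,
    base: SimConfig,
    master_seed: int,
    seeds_per_design: int = 5,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Simulate every (design, replicate) pair; one results row each.

    Replicate seeds derive deterministically from
    (master_seed, design_index, replicate).  Failures are logged and
    excluded.  With ``out_dir`` set, results stream to
    ``out_dir/results.csv`` and completed rows are skipped on re-run.
    """
    out_path = None
    done: set[tuple[int, int]] = set()
    prior: pd.DataFrame | None = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        try:
            out_dir.mkdir(parents=True, exist_ok=True)
            probe = out_dir / ".write_probe"
            probe.write_text("")
            probe.unlink()
        except OSError as exc:
            raise DesignError(f"output location not writable: {out_dir}") from exc
        out_path = out_dir / "results.csv"
        if out_path.exists():
            prior = pd.read_csv(out_path)
            done = set(
                zip(prior["design_index"].astype(int), prior["replicate"].astype(int))
            )

    param_cols = [c for c in design.columns if c != "design_index"]
    rows: list[dict] = []
    for _, drow in design.iterrows():
        didx = int(drow["design_index"])
        params = {c: drow[c] for c in param_cols}
        for rep in range(seeds_per_design):
            if (didx, rep) in done:
                continue
            seed = derive_seed(master_seed, "simulate", didx, rep)
            record = {"design_index": didx, "replicate": rep, **params, "seed": seed}
            try:
                record.update(run_one(base, params, seed))
            except Exception as exc:  # noqa: BLE001 - batch robustness
                logger.warning("design %d rep %d failed: %s", didx, rep, exc)
                continue
            rows.append(record)

    results = pd.DataFrame(rows)
    if prior is not None and len(prior):
        results = pd.concat([prior, results], ignore_index=True)
        results = results.sort_values(["design_index", "replicate"]).reset_index(
            drop=True
        )
    if out_path is not None:
        results.to_csv(out_path, index=False)
        schema = {
            "columns": {
                c: str(results[c].dtype) for c in results.columns
            },
            "metric_columns": [c for c in METRIC_COLUMNS if c in results.columns],
            "rows": int(len(results)),
        }
        out_path.with_suffix(".schema.json").write_text(
            json.dumps(schema, indent=2)
        )
    return results


def label_suitability(
    results: pd.DataFrame, criteria: SuitabilityCriteria
) -> pd.DataFrame:
    """Add a boolean ``suitable`` column: pore P5 >= lo and P95 <= hi
    (plus the porosity band when set); rows without pores are unsuitable."""
    lo, hi = criteria.pore_window_um2
    labeled = results.copy()
    ok = (
        (labeled["pore_count"] > 0)
        & (labeled["pore_area_p5_um2"] >= lo)
        & (labeled["pore_area_p95_um2"] <= hi)
    )
    if criteria.porosity_band is not None:
        plo, phi = criteria.porosity_band
        ok &= labeled["surface_porosity"].between(plo, phi)
    labeled["suitable"] = ok.fillna(False)
    return labeled


def _feature_columns(results: pd.DataFrame) -> list[str]:
    skip = set(METRIC_COLUMNS) | {"design_index", "replicate", "seed", "suitable"}
    return [
        c
        for c in results.columns
        if c not in skip and pd.api.types.is_numeric_dtype(results[c])
    ]


def fit_results_regression_tree(
    results: pd.DataFrame,
    target: str = "surface_porosity",
    max_depth: int = 4,
    min_leaf: int = 5,
) -> TreeModel:
    feats = _feature_columns(results)
    if target not in results.columns:
        raise DesignError(f"unknown target column {target!r}")
    X = results[feats].to_numpy(dtype=float)
    y = results[target].to_numpy(dtype=float)
    keep = ~np.isnan(y)
    return fit_regression_tree(
        X[keep], y[keep], max_depth=max_depth, min_leaf=min_leaf,
        feature_names=feats,
    )


def label_and_fit_decision_tree(
    results: pd.DataFrame,
    criteria: SuitabilityCriteria | None = None,
    max_depth: int = 4,
    min_leaf: int = 5,
) -> tuple[pd.DataFrame, TreeModel]:
    """Label suitability then fit a Gini classification tree on the input
    parameters.  A single-class labeling yields a root-only tree."""
    criteria = criteria or SuitabilityCriteria()
    labeled = label_suitability(results, criteria)
    if labeled["suitable"].nunique() < 2:
        logger.warning(
            "all rows labeled %s: root-only decision tree",
            bool(labeled["suitable"].iloc[0]) if len(labeled) else "n/a",
        )
    feats = _feature_columns(labeled)
    X = labeled[feats].to_numpy(dtype=float)
    y = labeled["suitable"].to_numpy(dtype=int)
    tree = fit_classification_tree(
        X, y, max_depth=max_depth, min_leaf=min_leaf, feature_names=feats
    )
    return labeled, tree


def aggregate_designs(
    labeled: pd.DataFrame, criteria: SuitabilityCriteria | None = None
) -> pd.DataFrame:
    """Replicate-averaged metrics per design.

    Design-level suitability re-applies the criteria to the replicate-mean
    metrics (stabler than voting over per-replicate labels); without
    criteria it falls back to the majority of row labels, ties unsuitable.
    """
    param_cols = [
        c
        for c in labeled.columns
        if c not in set(METRIC_COLUMNS) | {"design_index", "replicate", "seed", "suitable"}
    ]
    agg: dict = {c: "mean" for c in METRIC_COLUMNS if c in labeled.columns}
    if "suitable" in labeled.columns:
        agg["suitable"] = "mean"
    agg["replicate"] = "count"
    g = labeled.groupby("design_index", sort=True)
    out = g.agg(agg).rename(columns={"replicate": "n_replicates"})
    out["porosity_sd"] = g["surface_porosity"].std(ddof=0)
    if criteria is not None:
        lo, hi = criteria.pore_window_um2
        ok = (
            (out["pore_count"] > 0)
            & (out["pore_area_p5_um2"] >= lo)
            & (out["pore_area_p95_um2"] <= hi)
        )
        if criteria.porosity_band is not None:
            plo, phi = criteria.porosity_band
            ok &= out["surface_porosity"].between(plo, phi)
        out["suitable"] = ok.fillna(False)
    elif "suitable" in out.columns:
        out["suitable"] = out["suitable"] > 0.5
    for c in param_cols:
        out[c] = g[c].first()
    return out.reset_index()


def select_optimum(
    labeled: pd.DataFrame, criteria: SuitabilityCriteria | None = None
) -> OptimumReport:
    """Among suitable designs (replicate-averaged), pick the minimal
    pore-area CV; ties broken by porosity closest to the suitable-set
    median, then by lowest design index."""
    criteria = criteria or SuitabilityCriteria()
    if "suitable" not in labeled.columns:
        labeled = label_suitability(labeled, criteria)
    per_design = aggregate_designs(labeled, criteria)
    suitable = per_design[per_design["suitable"]]
    if suitable.empty:
        raise DesignError(
            "no suitable design in the sweep; widen the design space or "
            "relax the pore window"
        )
    med_por = suitable["surface_porosity"].median()
    ranked = suitable.assign(
        _por_dist=(suitable["surface_porosity"] - med_por).abs()
    ).sort_values(
        ["pore_area_cv", "_por_dist", "design_index"],
        kind="stable",
    )
    best = ranked.iloc[0]
    param_cols = [
        c
        for c in labeled.columns
        if c
        not in set(METRIC_COLUMNS)
        | {"design_index", "replicate", "seed", "suitable"}
    ]
    return OptimumReport(
        design_index=int(best["design_index"]),
        parameters={c: _jsonable(best[c]) for c in param_cols if c in best.index},
        mean_surface_porosity=float(best["surface_porosity"]),
        porosity_sd=float(best["porosity_sd"]),
        pore_area_p5_um2=float(best["pore_area_p5_um2"]),
        pore_area_p95_um2=float(best["pore_area_p95_um2"]),
        pore_area_cv=float(best["pore_area_cv"]),
        n_replicates=int(best["n_replicates"]),
        n_suitable_designs=int(len(suitable)),
        criteria={
            "pore_window_um2": list(criteria.pore_window_um2),
            "porosity_band": (
                list(criteria.porosity_band) if criteria.porosity_band else None
            ),
        },
    )


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v
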