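"""End-to-end orchestration: load or simulate a score table, run the OPNMF
stability arm and the PCA/EFA arm on the full sample and declared subgroups,
and emit comparable, fully reproducible reports."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .baselines import (
    correlation_matrix,
    efa_fit,
    max_identifiable_factors,
    parallel_analysis,
    pca_loadings,
    promax_rotate,
    scree_eigenvalues,
)
from .opnmf import opnmf_fit
from .scores import ScoreMatrix
from .stability import (
    adjusted_rand_index,
    run_stability,
    select_rank,
    variation_of_information,
)

logger = logging.getLogger(__name__)


@dataclass
class SubgroupSpec:
    """One subgroup: subjects where ``column`` satisfies ``op``/``value``
    (op in {eq, le, gt})."""

    label: str
    column: str
    op: str = "eq"
    value: object = None

    def mask(self, sm: ScoreMatrix) -> np.ndarray:
        vals = _subject_attribute(sm, self.column)
        if self.op == "eq":
            return np.asarray([str(v) == str(self.value) for v in vals])
        arr = np.asarray(vals, dtype=float)
        if self.op == "le":
            return arr <= float(self.value)
        if self.op == "gt":
            return arr > float(self.value)
        raise ValueError(f"unknown subgroup op {self.op!r}")


@dataclass
class AnalysisConfig:
    """Everything needed to re-run an analysis bit-identically."""

    seed: int
    input_path: str | None = None
    synthetic: dict | None = None  # kwargs for datasets.generate_* plus "kind"
    rank_range: tuple[int, int] = (2, 9)
    n_splits: int = 10_000
    subgroups: list[SubgroupSpec] = field(default_factory=list)
    methods: dict = field(
        default_factory=lambda: {"opnmf": True, "pca": True, "efa": True}
    )
    pa_settings: dict = field(default_factory=lambda: {"n_sim": 1000, "percentile": 95.0})
    opnmf_params: dict = field(default_factory=dict)
    out_dir: str | None = None
    make_plots: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        subs = [SubgroupSpec(**s) if isinstance(s, dict) else s for s in d.pop("subgroups", [])]
        if "rank_range" in d:
            d["rank_range"] = tuple(d["rank_range"])
        cfg = cls(subgroups=subs, **d)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "input_path": self.input_path,
            "synthetic": self.synthetic,
            "rank_range": list(self.rank_range),
            "n_splits": self.n_splits,
            "subgroups": [vars(s) for s in self.subgroups],
            "methods": self.methods,
            "pa_settings": self.pa_settings,
            "opnmf_params": self.opnmf_params,
            "make_plots": self.make_plots,
        }
        return d


def load_scores(path, sep: str | None = None, **kwargs) -> ScoreMatrix:
    """Read a subjects x items CSV/TSV into a ScoreMatrix.

    Complete-case rule: subjects with any missing item score are dropped and
    the exclusion count is logged.  Negative scores are rejected naming the
    offending cell.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.columns.size < 3:
        raise ValueError("score table must have a header with id and item columns")
    return ScoreMatrix.from_frame(df, **kwargs)


def _subject_attribute(sm: ScoreMatrix, column: str) -> list:
    if column.lower() in ("group", "gender", "sex") and sm.group_labels is not None:
        return [sm.group_labels.get(s, "") for s in sm.subject_ids]
    extra = sm.metadata.get("extra_columns", {})
    for name, vals in extra.items():
        if name.lower() == column.lower():
            return list(vals)
    raise ValueError(f"no subject metadata column {column!r}")


def _materialize_input(config: AnalysisConfig) -> ScoreMatrix:
    if config.input_path is not None:
        return load_scores(config.input_path)
    if config.synthetic is None:
        raise ValueError("config must provide either input_path or a synthetic block")
    spec = dict(config.synthetic)
    kind = spec.pop("kind", "flat")
    spec.setdefault("seed", config.seed)
    if kind == "flat":
        sm, _ = datasets.generate_scores(**spec)
    elif kind == "hierarchical":
        sm, _ = datasets.generate_hierarchical(**spec)
    elif kind == "subgroups":
        sm, _ = datasets.generate_subgroups(**spec)
    elif kind == "null":
        sm = datasets.generate_null(**spec)
    else:
        raise ValueError(f"unknown synthetic kind {kind!r}")
    return sm


def compare_partitions(partitions: dict[str, np.ndarray]):
    """Pairwise ARI and VI tables across labelled partitions of one item set."""
    labels = list(partitions)
    sizes = {len(np.asarray(p)) for p in partitions.values()}
    if len(sizes) > 1:
        raise ValueError("all partitions must be defined on the same item set")
    ari = pd.DataFrame(index=labels, columns=labels, dtype=float)
    vi = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for a in labels:
        for b in labels:
            ari.loc[a, b] = adjusted_rand_index(partitions[a], partitions[b])
            vi.loc[a, b] = variation_of_information(partitions[a], partitions[b])
    return ari, vi


def _analyse_sample(sm: ScoreMatrix, config: AnalysisConfig, seed: int) -> dict:
    out: dict = {"n_subjects": sm.n_subjects, "n_items": sm.n_items}
    ranks = range(config.rank_range[0], config.rank_range[1] + 1)

    if config.methods.get("opnmf", True):
        stab = run_stability(
            sm,
            ranks=ranks,
            n_splits=config.n_splits,
            seed=seed,
            opnmf_params=config.opnmf_params,
        )
        k_star, table = select_rank(stab)
        final = opnmf_fit(sm, k_star, **{
            k: v for k, v in config.opnmf_params.items() if k in ("init", "max_iter", "tol")
        })
        out["opnmf"] = {
            "stability": stab,
            "criterion_table": table,
            "k_star": k_star,
            "solution": final,
            "partition": final.partition,
        }

    if config.methods.get("pca", True) or config.methods.get("efa", True):
        R = correlation_matrix(sm)
        out["scree"] = scree_eigenvalues(R)

    if config.methods.get("pca", True):
        pa = parallel_analysis(
            sm, basis="pca-eigen", seed=seed + 1, **config.pa_settings
        )
        k_pca = max(pa.k_parallel or 0, 1)
        L = pca_loadings(R, k_pca, item_labels=sm.item_labels)
        rotated = promax_rotate(L) if k_pca > 1 else L
        out["pca"] = {
            "parallel": pa,
            "k": k_pca,
            "loadings": rotated,
            "partition": _partition_of(rotated),
        }

    if config.methods.get("efa", True):
        pa = parallel_analysis(
            sm, basis="efa-eigen", seed=seed + 2, **config.pa_settings
        )
        k_efa = int(np.clip(pa.k_parallel or 0, 1, max_identifiable_factors(sm.n_items)))
        efa = efa_fit(R, k_efa, sm.n_subjects, method="minres", item_labels=sm.item_labels)
        rotated = promax_rotate(efa) if k_efa > 1 else efa
        rotated.fit_stats = efa.fit_stats
        out["efa"] = {
            "parallel": pa,
            "k": k_efa,
            "loadings": rotated,
            "tli": efa.fit_stats["tli"],
            "partition": _partition_of(rotated),
        }
    return out


def _partition_of(L) -> np.ndarray:
    from .baselines import assign_items_from_loadings

    return assign_items_from_loadings(L)


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every enabled method on the full sample and each subgroup.

    Returns a nested report dict; when ``config.out_dir`` is set, writes
    TSV/JSON artifacts plus a manifest sufficient to re-run bit-identically.
    """
    sm = _materialize_input(config)
    report: dict = {"config": config.to_dict(), "samples": {}}
    report["samples"]["full"] = _analyse_sample(sm, config, seed=config.seed)

    for i, spec in enumerate(config.subgroups):
        mask = spec.mask(sm)
        idx = np.flatnonzero(mask)
        if idx.size < 6:
            logger.warning("subgroup %r has %d subjects (< 6): skipped", spec.label, idx.size)
            continue
        sub = sm.subset(idx, name=spec.label)
        report["samples"][spec.label] = _analyse_sample(
            sub, config, seed=config.seed + 1000 * (i + 1)
        )

    # cross-method (within sample) and cross-sample (per method) agreement
    comparisons = {}
    for name, res in report["samples"].items():
        parts = {
            m: res[m]["partition"] for m in ("opnmf", "pca", "efa") if m in res
        }
        if len(parts) >= 2:
            ari, vi = compare_partitions(parts)
            comparisons[f"methods_{name}"] = {"ari": ari, "vi": vi}
    opnmf_parts = {
        name: res["opnmf"]["partition"]
        for name, res in report["samples"].items()
        if "opnmf" in res
    }
    if len(opnmf_parts) >= 2:
        ari, vi = compare_partitions(opnmf_parts)
        comparisons["samples_opnmf"] = {"ari": ari, "vi": vi}
    report["comparisons"] = comparisons

    if config.out_dir is not None:
        _write_report(report, sm, config)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_report(report: dict, sm: ScoreMatrix, config: AnalysisConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"samples": {}}
    for name, res in report["samples"].items():
        s: dict = {"n_subjects": res["n_subjects"]}
        if "opnmf" in res:
            stab = res["opnmf"]["stability"]
            stab.to_tidy().to_csv(out / f"{name}_stability.tsv", sep="\t", index=False)
            res["opnmf"]["criterion_table"].to_csv(out / f"{name}_criteria.tsv", sep="\t")
            sol = res["opnmf"]["solution"]
            basis = pd.DataFrame(
                sol.basis,
                index=sm.item_labels,
                columns=[f"factor_{j + 1}" for j in range(sol.k)],
            )
            basis.index.name = "item"
            basis.to_csv(out / f"{name}_opnmf_basis.tsv", sep="\t")
            s["opnmf"] = {
                "k_star": res["opnmf"]["k_star"],
                "partition": res["opnmf"]["partition"],
                "final_objective": float(sol.objective_trace[-1]),
            }
        for m in ("pca", "efa"):
            if m in res:
                L = res[m]["loadings"]
                df = pd.DataFrame(
                    L.loadings,
                    index=L.item_labels or sm.item_labels,
                    columns=[f"factor_{j + 1}" for j in range(L.k)],
                )
                df.index.name = "item"
                df.to_csv(out / f"{name}_{m}_loadings.tsv", sep="\t")
                s[m] = {
                    "k": res[m]["k"],
                    "k_parallel": res[m]["parallel"].k_parallel,
                    "partition": res[m]["partition"],
                }
                if m == "efa":
                    s[m]["tli"] = res[m]["tli"]
        if "scree" in res:
            s["scree"] = {
                "eigenvalues": res["scree"].eigenvalues,
                "k_scree": res["scree"].k_scree,
            }
        summary["samples"][name] = s
    for cname, tables in report["comparisons"].items():
        tables["ari"].to_csv(out / f"compare_{cname}_ari.tsv", sep="\t")
        tables["vi"].to_csv(out / f"compare_{cname}_vi.tsv", sep="\t")
    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=1, sort_keys=True)
    manifest = {
        "config": report["config"],
        "n_items": sm.n_items,
        "n_subjects": sm.n_subjects,
        "item_labels": sm.item_labels,
        "versions": _versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=1, sort_keys=True)
    if config.make_plots:
        from . import plots

        for name, res in report["samples"].items():
            if "opnmf" in res:
                fig = plots.stability_curves(res["opnmf"]["stability"])
                fig.savefig(out / f"{name}_stability.png", dpi=120)
            if "pca" in res:
                fig = plots.parallel_analysis_plot(res["pca"]["parallel"])
                fig.savefig(out / f"{name}_pca_parallel.png", dpi=120)
            if "efa" in res:
                fig = plots.parallel_analysis_plot(res["efa"]["parallel"])
                fig.savefig(out / f"{name}_efa_parallel.png", dpi=120)


def _versions() -> dict:
    import scipy
    import sklearn

    from . import __version__

    return {
        "opnmfkit": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
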