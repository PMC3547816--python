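"""End-to-end orchestration: metrics -> timeline join -> trends -> report.

A run starts either from real inputs (a directory of single-domain PDB
files, a per-domain annotation TSV with sccs strings, and a rooted Newick
tree over families) or from a synthetic specification, and produces a
domain catalog, the family-level trend fits, the binned length analysis per
epoch with bootstrap SEMs, the fold-class analysis, the fast-folder screen,
and a JSON run report.  All randomness flows from the single configured
seed; re-running an identical configuration reproduces every numeric output
exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contact_metrics import ContactParams, build_contact_map, smco, tightness
from .structure_io import DomainCatalog, build_catalog, parse_sccs, read_structure
from .synthetic_data import SyntheticSpec, gen_catalog
from .timeline import ClockModel, clock_transform, node_distances, read_tree, timeline_frame
from .trend_stats import (
    TrendConfig,
    binned_length_analysis,
    class_analysis,
    loess_fit,
    resample_sem,
    screen_fast_folders,
    segmented_linear,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "analyze_catalog", "domain_metrics"]

logger = logging.getLogger("foldability")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one of (``synthetic``) or (``structures_dir`` + ``annotations`` +
    ``tree``) must be provided.
    """

    synthetic: SyntheticSpec | None = None
    structures_dir: str | None = None
    annotations: str | None = None
    tree: str | None = None
    contact_params: ContactParams = field(default_factory=ContactParams)
    clock: ClockModel = field(default_factory=ClockModel)
    trend: TrendConfig = field(default_factory=TrendConfig)
    out_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        real = all(v is not None for v in (self.structures_dir, self.annotations, self.tree))
        some_real = any(v is not None for v in (self.structures_dir, self.annotations, self.tree))
        if self.synthetic is not None and some_real:
            raise ValueError("provide either a synthetic spec or real inputs, not both")
        if self.synthetic is None and not real:
            raise ValueError("real inputs need structures_dir, annotations and tree together")

    def fingerprint(self) -> str:
        parts = {
            "mode": "synthetic" if self.synthetic is not None else "real",
            "synthetic": asdict(self.synthetic) if self.synthetic else None,
            "structures_dir": self.structures_dir,
            "annotations": self.annotations,
            "tree": self.tree,
            "contact_params": self.contact_params.fingerprint(),
            "clock": self.clock.fingerprint(),
            "trend": self.trend.fingerprint(),
        }
        blob = json.dumps(parts, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def domain_metrics(path, chain=None, params: ContactParams | None = None) -> dict:
    """Contact metrics of one PDB file: L, N_c, relCO, SMCO, tightness."""
    from .contact_metrics import relative_contact_order

    params = params or ContactParams()
    s = read_structure(path, chain=chain)
    cm = build_contact_map(s, params)
    return {
        "domain_id": s.domain_id,
        "length": cm.L,
        "n_contacts": cm.n_contacts,
        "rel_co": relative_contact_order(cm),
        "smco": smco(cm),
        "tightness": tightness(cm),
        "params": params.fingerprint(),
    }


def _build_real_catalog(cfg: RunConfig) -> tuple[DomainCatalog, pd.DataFrame]:
    ann = pd.read_csv(cfg.annotations, sep="\t")
    required = {"domain_id", "filename", "sccs"}
    missing = required - set(ann.columns)
    if missing:
        raise PipelineError(f"annotations missing columns: {sorted(missing)}")
    tree = read_tree(cfg.tree)
    entries = clock_transform(node_distances(tree), cfg.clock)
    tl = timeline_frame(entries, cfg.clock)
    base = Path(cfg.structures_dir)
    records = []
    for row in ann.itertuples(index=False):
        chain = getattr(row, "chain", None)
        if isinstance(chain, float) and np.isnan(chain):
            chain = None
        metrics = domain_metrics(base / row.filename, chain=chain, params=cfg.contact_params)
        records.append((row.domain_id, parse_sccs(row.sccs), metrics))
    catalog = build_catalog(records, tl)
    return catalog, tl


def _synthetic_timeline(catalog: DomainCatalog) -> pd.DataFrame:
    fm = catalog.family_means
    return pd.DataFrame({"taxon": fm["family"], "node_count": -1,
                         "nd": np.nan, "age": fm["age"]})


def _trend_dict(fit) -> dict:
    return {"delta": fit.delta, "p_value": fit.p_value, "edf": fit.edf}


def _segment_dict(seg) -> dict | None:
    if seg is None:
        return None
    return {"slope": seg.slope, "intercept": seg.intercept,
            "p_slope": seg.p_slope, "stderr": seg.stderr, "n": seg.n}


def analyze_catalog(catalog: DomainCatalog, trend: TrendConfig,
                    origin_age: float = 3.8) -> dict:
    """All trend analyses on one catalog; returns the report sections.

    Family-mean SMCO (and tightness) are smoothed against age with LOESS;
    segmented regression is fitted on the forward-time axis
    ``t = origin_age - age`` with the breakpoint converted accordingly, so
    reported slopes are SMCO per Gya elapsed (negative = folding speeding
    up).  The binned length analysis and its bootstrap SEMs, the fold-class
    analysis and the fast-folder screen run on the domain-level catalog.
    """
    report: dict = {}
    fm = catalog.family_means
    ages = fm["age"].to_numpy(dtype=float)

    fit = loess_fit(ages, fm["smco"].to_numpy(dtype=float), trend)
    report["family_trend"] = _trend_dict(fit)
    if fm["tightness"].notna().all():
        tfit = loess_fit(ages, fm["tightness"].to_numpy(dtype=float), trend)
        report["tightness_trend"] = _trend_dict(tfit)

    t_fwd = origin_age - ages
    seg = segmented_linear(t_fwd, fm["smco"].to_numpy(dtype=float),
                           origin_age - trend.breakpoint)
    report["segmented"] = {
        "axis": "forward_time",
        "early": _segment_dict(seg.below),  # t < t_break: before the big bang
        "late": _segment_dict(seg.above),
    }

    epochs = {"early": (trend.breakpoint, origin_age), "late": (0.0, trend.breakpoint)}
    report["epoch_trends"] = {}
    for name, (lo, hi) in epochs.items():
        mask = (ages >= lo) & (ages <= hi)
        if mask.sum() >= max(10, 5 * trend.degree):
            efit = loess_fit(ages[mask], fm.loc[mask, "smco"].to_numpy(dtype=float), trend)
            report["epoch_trends"][name] = _trend_dict(efit)
        else:
            report["epoch_trends"][name] = None

    report["binned"] = {}
    for name, epoch in epochs.items():
        try:
            summary = binned_length_analysis(catalog, epoch, trend)
        except ValueError:
            report["binned"][name] = None
            continue
        sems, dropped = resample_sem(
            catalog,
            lambda df, e=epoch: binned_length_analysis(df, e, trend).percentages,
            n_resample=trend.n_resample,
            seed=trend.seed,
        )
        summary.sem = sems
        report["binned"][name] = {
            "percentages": summary.percentages,
            "sem": sems,
            "n_domains": summary.n_domains,
            "n_bins": len(summary.table),
            "dropped_replicates": dropped,
        }
        report.setdefault("_bin_tables", {})[name] = summary.table

    cs = class_analysis(catalog, trend, origin_age=origin_age)
    report["classes"] = {
        "per_class": {
            letter: {
                name: {"percentages": bs.percentages, "n_domains": bs.n_domains}
                for name, bs in by_epoch.items()
            }
            for letter, by_epoch in cs.per_class.items()
        },
        "pairwise_wilcoxon_p": {f"{a}-{b}": p for (a, b), p in cs.pairwise_p.items()},
        "excluded": cs.excluded,
    }

    screen = screen_fast_folders(catalog)
    report["fast_folders"] = {
        "threshold": screen.threshold,
        "n_below": len(screen.families),
        "fraction": screen.fraction,
        "n_families_total": screen.n_families_total,
    }
    report["_screen_table"] = screen.families
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and (optionally) write all outputs.

    Stage order: catalog construction, trend analyses, fast-folder screen,
    report.  On stage failure any partially written outputs are removed and
    a :class:`PipelineError` naming the stage is raised.
    """
    logging.basicConfig(stream=sys.stderr, level=cfg.log_level)
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    written: list[Path] = []

    def _write(name: str, writer) -> None:
        if out_dir is None:
            return
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / name
        writer(path)
        written.append(path)

    stage = "catalog"
    try:
        if cfg.synthetic is not None:
            logger.info("stage catalog: generating synthetic catalog (seed=%d)",
                        cfg.synthetic.seed)
            catalog, truth = gen_catalog(cfg.synthetic)
            tl = _synthetic_timeline(catalog)
        else:
            logger.info("stage catalog: reading structures from %s", cfg.structures_dir)
            catalog, tl = _build_real_catalog(cfg)
            truth = None

        stage = "trends"
        logger.info("stage trends: %d domains, %d families",
                    len(catalog.domains), len(catalog.family_means))
        report = analyze_catalog(catalog, cfg.trend, origin_age=cfg.clock.origin_age)

        stage = "report"
        fingerprint = cfg.fingerprint()
        bin_tables = report.pop("_bin_tables", {})
        screen_table = report.pop("_screen_table", None)
        report.update(
            {
                "config_hash": fingerprint,
                "seed": cfg.trend.seed if cfg.synthetic is None else cfg.synthetic.seed,
                "n_domains": int(len(catalog.domains)),
                "n_families": int(len(catalog.family_means)),
                "unmapped_domains": len(catalog.unmapped),
                "versions": {"foldability": __version__, "numpy": np.__version__,
                             "pandas": pd.__version__},
            }
        )
        if truth is not None:
            report["planted_truth"] = truth

        _write("catalog.tsv", catalog.to_tsv)
        _write("family_means.tsv", lambda p: catalog.family_means.to_csv(p, sep="\t", index=False))
        _write("timeline.tsv", lambda p: tl.to_csv(p, sep="\t", index=False))
        for name, table in bin_tables.items():
            _write(f"bins_{name}.tsv",
                   lambda p, t=table: t.to_csv(p, sep="\t", index=False))
        if screen_table is not None:
            _write("fast_folders.tsv",
                   lambda p: screen_table.to_csv(p, sep="\t", index=False))
        _write("report.json",
               lambda p: p.write_text(json.dumps(report, indent=2, sort_keys=True,
                                                 default=str) + "\n"))
        logger.info("pipeline complete (config %s)", fingerprint)
        return report
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
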