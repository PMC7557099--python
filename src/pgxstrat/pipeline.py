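"""End-to-end driver: simulate/load -> group -> diverge -> structure -> risk.

Runs the stages in dependency order, writes each stage's tabular
outputs plus a single machine-readable ``report.json``, and derives
every stage seed from the single run seed so a rerun with the same
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import divergence as dv
from . import grouping as gp
from . import regression as rg
from . import risk as rk
from . import structure as st
from .cohort import Cohort, read_tables, write_tables
from .simulate import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    sim: SimConfig | None = None
    cohort_dir: str | Path | None = None  # read TSVs from here if sim is None
    k: int = 3
    restarts: int = 100
    alpha: float = 0.05
    fdr_q: float = 0.05
    seed: int = 0
    outdir: str | Path = "pgxstrat_out"

    def validate(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0,1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.sim is None and self.cohort_dir is None:
            raise ValueError("either a simulation config or a cohort directory")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonable) + "\n")


def load_cohort(cohort_dir: str | Path) -> Cohort:
    d = Path(cohort_dir)
    cohort, _ = read_tables(
        d / "genotypes.tsv", d / "ancestry.tsv", d / "sire.tsv", d / "pgx.tsv"
    )
    return cohort


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report dictionary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": {
            "k": config.k,
            "restarts": config.restarts,
            "alpha": config.alpha,
            "fdr_q": config.fdr_q,
            "seed": config.seed,
        }
    }

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    # ----- cohort --------------------------------------------------
    t0 = stage("cohort")
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        cohort, truth = simulate_cohort(sim)
        write_tables(cohort, outdir)
        _write_json(
            outdir / "truth.json",
            {
                "group_names": list(truth.group_names),
                "group_sizes": list(truth.group_sizes),
                "ancestral_freqs": truth.ancestral_freqs,
                "expected_group_freqs": truth.expected_group_freqs,
                "pgx_indices": truth.pgx_indices,
                "pgx_divergent_indices": truth.pgx_divergent_indices,
            },
        )
        report["parameters"]["simulation"] = {
            k: v for k, v in dataclasses.asdict(sim).items()
            if not isinstance(v, np.ndarray)
        }
    else:
        cohort = load_cohort(config.cohort_dir)
    if cohort.sire_labels is None or cohort.ancestry is None:
        raise ValueError("pipeline needs SIRE labels and ancestry fractions")
    report["cohort"] = {
        "n_samples": cohort.n_samples,
        "n_variants": cohort.n_variants,
        "n_pgx_variants": int(cohort.pgx_mask.sum()),
    }
    logger.info("cohort ready in %.1fs", time.perf_counter() - t0)

    # ----- GA grouping ---------------------------------------------
    t0 = stage("ga-groups")
    grouping = gp.cluster_ancestry(
        cohort.ancestry, k=config.k, restarts=config.restarts, seed=config.seed + 1
    )
    concord = gp.align_and_concord(grouping, cohort.sire_labels)
    pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "ga_group": grouping.assignments,
            "agreement": grouping.restart_agreement,
        }
    ).to_csv(outdir / "ga_assignments.tsv", sep="\t", index=False)
    _write_json(outdir / "concordance.json", concord.to_dict())
    report["concordance"] = concord.to_dict()
    logger.info("ga-groups done in %.1fs", time.perf_counter() - t0)

    # ----- divergence ----------------------------------------------
    t0 = stage("divergence")
    scan = dv.group_vs_complement_scan(
        cohort, cohort.sire_labels, pgx_only=True, fdr_q=config.fdr_q
    )
    scan.to_csv(outdir / "divergence.tsv", sep="\t", index=False, float_format="%.10g")
    summary = dv.summarize_divergence(scan)
    background = dv.pgx_background_comparison(cohort, cohort.sire_labels)
    summary["mean_pooled_freq_pgx"] = float(
        background.loc[background.pgx, "pooled_freq"].mean()
    )
    summary["mean_pooled_freq_background"] = float(
        background.loc[~background.pgx, "pooled_freq"].mean()
    ) if (~background.pgx).any() else None
    _write_json(outdir / "divergence_summary.json", summary)
    report["divergence"] = summary
    logger.info("divergence done in %.1fs", time.perf_counter() - t0)

    # ----- PGx structure -------------------------------------------
    t0 = stage("pgx-structure")
    dist = st.pgx_distance(cohort)
    embedding = st.classical_mds(dist, dims=2)
    pgx_grouping, pgx_concord = st.cluster_embedding_and_correspond(
        embedding, config.k, cohort.sire_labels,
        restarts=config.restarts, seed=config.seed + 2,
    )
    pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "dim1": embedding[:, 0],
            "dim2": embedding[:, 1],
            "cluster": pgx_grouping.assignments,
            "sire": cohort.sire_labels,
        }
    ).to_csv(outdir / "mds.tsv", sep="\t", index=False, float_format="%.10g")
    _write_json(outdir / "pgx_correspondence.json", pgx_concord.to_dict())
    report["pgx_correspondence"] = pgx_concord.to_dict()
    logger.info("pgx-structure done in %.1fs", time.perf_counter() - t0)

    # ----- risk ------------------------------------------------------
    t0 = stage("risk")
    per_variant, per_group = rk.risk_table(
        cohort, cohort.sire_labels, alpha=config.alpha
    )
    per_variant.to_csv(outdir / "risk_table.tsv", sep="\t", index=False,
                       float_format="%.10g")
    gain = rk.info_gain_by_group(per_group)
    gain.to_csv(outdir / "info_gain_by_group.tsv", sep="\t", index=False,
                float_format="%.10g")
    report["info_gain_median_per_100"] = {
        row.group: row.median for row in gain.itertuples(index=False)
    }
    logger.info("risk done in %.1fs", time.perf_counter() - t0)

    # ----- SIRE vs GA regression -------------------------------------
    t0 = stage("compare-sire-ga")
    slopes = rg.compare_sire_ga_slopes(
        cohort, cohort.sire_labels, grouping.assignments, concord.mapping
    )
    slope_rows = []
    for (a, b), stt in slopes.items():
        slope_rows.append(
            {
                "pair": f"{a}-{b}", "beta": stt.beta, "intercept": stt.intercept,
                "se": stt.se, "p0": stt.p0, "p1": stt.p1, "d": stt.d,
            }
        )
    pd.DataFrame(slope_rows).to_csv(
        outdir / "slope_tests.tsv", sep="\t", index=False, float_format="%.10g"
    )
    report["slope_tests"] = {r["pair"]: {k: r[k] for k in ("beta", "p0", "p1", "d")}
                             for r in slope_rows}

    assoc_rows = []
    for variant in cohort.variants:
        if variant.pgx is None:
            continue
        for comp in ("european", "african", "native_american"):
            try:
                a = rg.ancestry_association(cohort, variant.variant_id, comp)
            except Exception:
                continue
            assoc_rows.append(
                {
                    "variant_id": a.variant_id, "component": a.ancestry_component,
                    "beta": a.beta, "se": a.se, "p_value": a.p_value, "n": a.n,
                }
            )
    pd.DataFrame(assoc_rows).to_csv(
        outdir / "ancestry_assoc.tsv", sep="\t", index=False, float_format="%.10g"
    )
    logger.info("compare-sire-ga done in %.1fs", time.perf_counter() - t0)

    _write_json(outdir / "report.json", report)
    return report
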