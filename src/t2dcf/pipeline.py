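"""End-to-end experiment orchestration on synthetic cohorts.

``run_experiment`` reproduces the full study shape: simulate a cohort,
stratified 70/30 split, train the two-sphere classifier (optionally with
FNR-constrained reduction of the low-risk sphere), select admissible
factuals, search counterfactuals, score the metric suite and characterize
the biomarker changes; every stage's outputs land in the run directory
together with a manifest holding all seeds and parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .characterize import characterize, format_summary_table, rank_sum_between_groups
from .metrics import evaluate_pairs
from .schema import Cohort, save_cohort, split_stratified
from .search import (
    CounterfactualPair,
    SearchConfig,
    generate_all,
    save_pairs,
    select_factuals,
)
from .simulate import GeneratorConfig, default_t2dm_config, generate_cohort
from .svdd import (
    SVDDHyperparams,
    evaluate,
    reduce_fnr,
    save_model,
    train_tc_svdd,
)

log = logging.getLogger("t2dcf")


@dataclass
class RunConfig:
    """Everything needed to re-execute a run bit-identically."""

    outdir: str = "t2dcf_run"
    seed: int = 42
    n_per_class: int = 1000
    train_fraction: float = 0.7
    hyperparams: SVDDHyperparams = field(default_factory=SVDDHyperparams)
    reduce: bool = False
    tau: float = 0.08
    shrink_step: float = 0.01
    coverage_floor: float = 0.35
    search: SearchConfig = field(default_factory=lambda: SearchConfig(L=2000))
    generator: GeneratorConfig | None = None
    knn_seed: int = 0


@dataclass
class RunResult:
    outdir: Path
    cohort: Cohort
    train: Cohort
    test: Cohort
    model: object
    pairs: list[CounterfactualPair]
    performance: dict
    metrics: dict
    manifest: dict


def run_experiment(config: RunConfig) -> RunResult:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    gen = config.generator or default_t2dm_config(
        n_per_class=config.n_per_class, seed=config.seed
    )
    gen = dataclasses.replace(gen, n_per_class=config.n_per_class, seed=config.seed)

    log.info("simulate: n_per_class=%d seed=%d", gen.n_per_class, gen.seed)
    cohort, gen_report = generate_cohort(gen)
    save_cohort(cohort, out / "cohort.csv")

    train, test = split_stratified(cohort, config.train_fraction, seed=config.seed)
    log.info("split: %d train / %d test", len(train), len(test))

    model = train_tc_svdd(train, config.hyperparams)
    if config.reduce:
        model = reduce_fnr(
            model, train, tau=config.tau, shrink_step=config.shrink_step,
            coverage_floor=config.coverage_floor,
        )
        log.info("reduction: %d steps, final FNR %.3f",
                 len(model.reduction_trace) - 1,
                 model.reduction_trace[-1]["fnr"])
    save_model(model, out / "model.json")

    perf = {
        "train": evaluate(model, train).to_dict(),
        "test": evaluate(model, test).to_dict(),
    }
    pd.DataFrame(perf).T.to_csv(out / "performance.csv")

    source = {"train": train, "test": test, "all": cohort}[
        config.search.factual_source
    ]
    factuals = select_factuals(model, source, config.search)
    log.info("factuals: %d admissible of %d high-risk",
             len(factuals), int((source.y == "highT2DM").sum()))

    pairs = generate_all(model, factuals, config.search)
    save_pairs(pairs, model.schema, out / "pairs.csv")

    report = evaluate_pairs(model, pairs, source, seed=config.knn_seed)
    with open(out / "metrics.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)

    summary, tests = characterize(pairs, model.schema)
    summary.to_csv(out / "summary.csv", index=False)
    if not summary.empty:
        format_summary_table(summary).to_csv(out / "summary_table.csv")
    tests.to_csv(out / "tests.csv", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_per_class": config.n_per_class,
        "train_fraction": config.train_fraction,
        "hyperparams": dataclasses.asdict(model.hyperparams),
        "reduce": config.reduce,
        "tau": config.tau if config.reduce else None,
        "shrink_step": config.shrink_step if config.reduce else None,
        "coverage_floor": config.coverage_floor if config.reduce else None,
        "search": dataclasses.asdict(config.search),
        "knn_seed": config.knn_seed,
        "generator_report": dataclasses.asdict(gen_report),
        "n_factuals": len(factuals),
        "n_pairs_available": sum(p.available for p in pairs),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return RunResult(
        outdir=out, cohort=cohort, train=train, test=test, model=model,
        pairs=pairs, performance=perf, metrics=report.to_dict(),
        manifest=manifest,
    )


def compare_canonical_vs_reduced(
    pairs_canonical: list[CounterfactualPair],
    pairs_reduced: list[CounterfactualPair],
    schema,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Side-by-side delta comparison restricted to common factuals.

    Only counterfactuals derived from factual ids present (and available)
    in both runs enter the comparison; per group x biomarker the two delta
    distributions are summarised side by side and compared with a
    two-sided rank-sum test.
    """
    from .characterize import compute_deltas

    avail_a = {p.factual_id for p in pairs_canonical if p.available}
    avail_b = {p.factual_id for p in pairs_reduced if p.available}
    common = avail_a & avail_b
    if not common:
        raise ValueError("the two runs share no available factual ids")

    da = compute_deltas([p for p in pairs_canonical if p.factual_id in common], schema)
    db = compute_deltas([p for p in pairs_reduced if p.factual_id in common], schema)
    biomarkers = [c for c in da.columns if c not in ("factual_id", "group")]

    rows, tests = [], []
    for grp in sorted(set(da["group"]) & set(db["group"])):
        sa = da[da["group"] == grp]
        sb = db[db["group"] == grp]
        for b in biomarkers:
            va, vb = sa[b].to_numpy(float), sb[b].to_numpy(float)
            rows.append({
                "group": grp, "biomarker": b, "n": len(va),
                "median_canonical": float(np.median(va)),
                "median_reduced": float(np.median(vb)),
            })
            if len(va) >= 4 and len(vb) >= 4:
                r = rank_sum_between_groups(va, vb, b, (f"{grp}:canonical",
                                                        f"{grp}:reduced"))
                tests.append({"group": grp, "biomarker": b,
                              "statistic": r.statistic, "p_value": r.p_value})
    return pd.DataFrame(rows), pd.DataFrame(tests)
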