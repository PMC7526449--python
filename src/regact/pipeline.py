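"""End-to-end orchestration: score -> intrinsic -> correlate -> pairs -> network.

One YAML-serialisable config drives the whole analysis over simulated or
on-disk cohorts. Every stage writes its table under the output directory
and a ``manifest.json`` records parameters, seeds and artifact checksums so
a rerun with the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .base_scoring import base_activity, normalize_expression
from .clinical_correlation import aggregate_rank, correlate_mrss
from .intrinsic_selection import intrinsic_fdr, select_intrinsic, wb_table
from .io_formats import (
    ActivityMatrix,
    ClinicalTable,
    ExpressionMatrix,
    extract_symbol,
    preprocess_probes,
    read_clinical,
    read_expression,
    read_gmt,
    write_clinical,
    write_expression,
    write_gmt,
    write_scores,
)
from .network import build_network, export_network, sign_category
from .subgroup_analysis import (
    assign_groups,
    fvc_decline_test,
    ild_fold_change_scan,
    pair_results_frame,
    pairwise_severity_scan,
)
from .synthetic_data import SimulationConfig, default_config, simulate_multicohort

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # inputs: simulate n cohorts, or load from disk
    n_cohorts: int = 4
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    expression_paths: list[str] = field(default_factory=list)
    clinical_paths: list[str] = field(default_factory=list)
    gmt_path: str | None = None
    dialects: list[str] = field(default_factory=list)
    # stage parameters (defaults mirror the study's cutoffs)
    n_perm_base: int = 200
    n_perm_wb: int = 500
    intrinsic_fdr_threshold: float = 0.02
    intrinsic_min_datasets: int = 3
    top_k: int = 50
    pair_q_threshold: float = 0.01
    ild_q_threshold: float = 0.05
    ild_fc_threshold: float = 1.5
    fvc_min_months: float = 36.0
    pair_subset: str = "fibroproliferative"

    def validate(self) -> None:
        if self.simulate:
            if self.n_cohorts < 2:
                raise PipelineError("need >=2 cohorts")
        else:
            if len(self.expression_paths) != len(self.clinical_paths):
                raise PipelineError("expression/clinical path counts differ")
            if len(self.expression_paths) < 2:
                raise PipelineError("need >=2 cohorts")
            if not self.gmt_path:
                raise PipelineError("gmt_path required when not simulating")
        n = self.n_cohorts if self.simulate else len(self.expression_paths)
        if self.intrinsic_min_datasets > n:
            raise PipelineError(
                f"intrinsic_min_datasets={self.intrinsic_min_datasets} exceeds "
                f"cohort count {n}"
            )
        for name in (
            "intrinsic_fdr_threshold",
            "pair_q_threshold",
            "ild_q_threshold",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise PipelineError(f"{name}={v} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, stage: int) -> int:
    return int(
        np.random.SeedSequence(master, spawn_key=(stage,)).generate_state(1)[0]
        % (2**31)
    )


def _load_cohorts(cfg: PipelineConfig):
    if cfg.simulate:
        sim_seed = _stage_seed(cfg.seed, 0)
        base = default_config(seed=sim_seed, **cfg.sim_overrides)
        cfgs = [
            dataclasses.replace(base, seed=_stage_seed(cfg.seed, 10 + i))
            for i in range(cfg.n_cohorts)
        ]
        cohorts = simulate_multicohort(cfgs, shared_truth=True)
        sets = cohorts[0][1]
        return (
            [(em, ct) for em, _, ct, _ in cohorts],
            sets,
            [t for _, _, _, t in cohorts],
        )
    sets = read_gmt(cfg.gmt_path)
    cohorts = []
    for i, (epath, cpath) in enumerate(
        zip(cfg.expression_paths, cfg.clinical_paths)
    ):
        dialect = cfg.dialects[i] if i < len(cfg.dialects) else "two_channel_log_ratio"
        pm = read_expression(epath, dialect=dialect)
        cohorts.append((preprocess_probes(pm), read_clinical(cpath)))
    return cohorts, sets, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order and return the artifact manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def save(name: str) -> Path:
        path = out / name
        artifacts.append(name)
        return path

    cohorts, sets, truths = _load_cohorts(cfg)
    write_gmt(sets, save("regulator_sets.gmt"))

    # stage 1: normalize + activity per cohort
    activities: list[ActivityMatrix] = []
    clinicals: list[ClinicalTable] = []
    for i, (em, ct) in enumerate(cohorts):
        logger.info("scoring cohort %d (%d samples)", i, em.values.shape[1])
        normalized = normalize_expression(em)
        am = base_activity(
            normalized, sets, n_perm=cfg.n_perm_base, seed=_stage_seed(cfg.seed, 1)
        )
        write_scores(am, save(f"activity_cohort{i}.tsv"))
        write_clinical(ct, save(f"clinical_cohort{i}.tsv"))
        activities.append(am)
        clinicals.append(ct)

    # stage 2: intrinsic regulator selection across cohorts
    per_dataset = {}
    for i, (am, ct) in enumerate(zip(activities, clinicals)):
        labels = ct.data.loc[am.samples, "subset"].to_numpy()
        per_dataset[f"cohort{i}"] = intrinsic_fdr(
            am,
            labels,
            n_perm=cfg.n_perm_wb,
            seed=_stage_seed(cfg.seed, 2),
            dataset=f"cohort{i}",
        )
    wb_table(per_dataset).to_csv(save("within_between.tsv"), sep="\t", index=False)
    intrinsic = select_intrinsic(
        per_dataset, cfg.intrinsic_fdr_threshold, cfg.intrinsic_min_datasets
    )
    pd.Series(intrinsic, name="regulator").to_csv(
        save("intrinsic_regulators.tsv"), sep="\t", index=False
    )

    # stage 3: MRSS correlation rankings per subset
    rankings = {}
    for subset in ("fibroproliferative", "inflammatory"):
        tables = {}
        for i, (am, ct) in enumerate(zip(activities, clinicals)):
            try:
                tables[f"cohort{i}"] = correlate_mrss(am, ct, subset)
            except ValueError:
                logger.warning("cohort %d lacks %s samples for PCC", i, subset)
        ranking = aggregate_rank(tables, method="mean", k=cfg.top_k)
        ranking.table.to_csv(save(f"ranking_{subset}.tsv"), sep="\t")
        rankings[subset] = ranking

    # stage 4: pairwise quadrant scan on the combined cohort
    combined_scores = pd.concat([am.scores for am in activities], axis=1)
    combined_am = ActivityMatrix(scores=combined_scores)
    combined_ct = ClinicalTable(data=pd.concat([c.data for c in clinicals]))
    pair_universe = [
        r
        for r in rankings[cfg.pair_subset].flagged("top50")
        if rankings[cfg.pair_subset].table.loc[r, "aggregate"] > 0
    ]
    subset_samples = combined_ct.subset_samples(cfg.pair_subset)
    subset_am = ActivityMatrix(scores=combined_am.scores[subset_samples])
    pairs = pairwise_severity_scan(
        subset_am, combined_ct, pair_universe, q_threshold=cfg.pair_q_threshold
    )
    pair_results_frame(pairs).to_csv(save("pairs.tsv"), sep="\t", index=False)

    # stage 5: ILD fold-change scan + FVC decline on the top pair
    ild_pairs = ild_fold_change_scan(
        subset_am,
        combined_ct,
        pair_universe,
        q_threshold=cfg.ild_q_threshold,
        fc_threshold=cfg.ild_fc_threshold,
    )
    pair_results_frame(ild_pairs).to_csv(save("ild_pairs.tsv"), sep="\t", index=False)
    fvc_rows = []
    if ild_pairs:
        top = ild_pairs[0]
        a = subset_am.scores.loc[top.pair[0]].to_numpy()
        b = subset_am.scores.loc[top.pair[1]].to_numpy()
        groups = dict(zip(subset_am.samples, assign_groups(a, b)))
        fvc = fvc_decline_test(combined_ct, groups, min_months=cfg.fvc_min_months)
        for g, res in fvc.items():
            fvc_rows.append(
                {
                    "pair": "|".join(top.pair),
                    "group": g,
                    "n": res.n,
                    "t": res.t_statistic,
                    "p": res.p_value,
                    "mean_decline": res.mean_decline,
                }
            )
    pd.DataFrame(fvc_rows).to_csv(save("fvc_decline.tsv"), sep="\t", index=False)

    # stage 6: regulator interaction network over the flagged regulators
    fib = rankings["fibroproliferative"].table["aggregate"]
    inf = rankings["inflammatory"].table["aggregate"]
    flagged = sorted(
        set(rankings["fibroproliferative"].flagged("top50"))
        | set(rankings["fibroproliferative"].flagged("bottom50"))
        | set(rankings["inflammatory"].flagged("top50"))
        | set(rankings["inflammatory"].flagged("bottom50"))
    )
    symbols = sorted(
        {sym for r in flagged if (sym := extract_symbol(r)) is not None}
    )
    annotations = {}
    for name in flagged:
        sym = extract_symbol(name)
        if sym is None:
            continue
        annotations[sym] = sign_category(
            float(fib[name]) if name in fib.index else None,
            float(inf[name]) if name in inf.index else None,
        )
    net = build_network(sets, symbols, annotations)
    if net.number_of_nodes():
        export_network(net, "graphml", save("network.graphml"))
        export_network(net, "edge_tsv", save("network_edges.tsv"))

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": dataclasses.asdict(cfg),
        "n_intrinsic": len(intrinsic),
        "n_pairs_significant": sum(p.significant for p in pairs),
        "n_ild_pairs": len(ild_pairs),
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
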