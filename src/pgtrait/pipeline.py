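"""End-to-end orchestration: classify -> stats -> events -> pagel -> clusters.

``run_pipeline`` executes the selected stages on an annotation cohort (and,
for the phylogenetic stages, a rooted Newick tree), writing one canonical
JSON report per stage plus a manifest recording the seed, the configuration
hash and package versions.  All JSON is written with sorted keys so reruns
with identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotation_io import Cohort, read_cohort
from .association_stats import (
    TwoByTwo,
    absence_pca,
    chisq_association,
    phi_correlation,
    pg_absence_regression,
)
from .annotation_io import FAMILIES
from .event_clustering import cluster_by_date, verify_clusters
from .geneset_classifier import (
    GeneSetRule,
    classify_cohort,
    confusion,
    metrics,
)
from .phylo_events import (
    CostScheme,
    Phylogeny,
    ancestral_parsimony,
    character_from_cohort,
    extract_events,
    read_newick,
)

log = logging.getLogger("pgtrait")

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    annotation_tsv: str
    output_dir: str
    tree_newick: str | None = None
    rule: GeneSetRule = field(default_factory=GeneSetRule)
    costs: CostScheme = field(default_factory=CostScheme)
    characters: tuple[str, ...] = ("GT51", "pg")
    n_sim: int = 99
    seed: int = 0
    stages: tuple[str, ...] = ("classify", "stats", "events", "pagel", "clusters")

    def as_dict(self) -> dict:
        return {
            "annotation_tsv": str(self.annotation_tsv),
            "tree_newick": None if self.tree_newick is None else str(self.tree_newick),
            "output_dir": str(self.output_dir),
            "rule": {
                "required_all": sorted(self.rule.required_all),
                "required_any": sorted(self.rule.required_any),
                "min_any": self.rule.min_any,
            },
            "costs": {"gain_cost": self.costs.gain_cost, "loss_cost": self.costs.loss_cost},
            "characters": list(self.characters),
            "n_sim": self.n_sim,
            "seed": self.seed,
            "stages": list(self.stages),
        }


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _metrics_dict(m) -> dict:
    return {k: v for k, v in m.as_dict().items()}


def _stage_classify(cohort: Cohort, cfg: PipelineConfig) -> dict:
    result = classify_cohort(cohort, cfg.rule)
    conf = confusion(result.predictions, cohort, positive_means="pg_present")
    report = {
        "per_genome": {
            gid: bool(pred) for gid, pred in zip(result.genome_ids, result.predictions)
        },
        "by_domain": {
            d: {"n": n, "set_positive": pos} for d, (n, pos) in result.by_domain.items()
        },
        "by_phylum": {
            f"{d}/{p}": {"n": n, "set_positive": pos}
            for (d, p), (n, pos) in result.by_phylum.items()
        },
        "confusion": {
            "tp": conf.tp,
            "fp": conf.fp,
            "tn": conf.tn,
            "fn": conf.fn,
            "excluded_unknown": conf.excluded_unknown,
        },
        "metrics": _metrics_dict(metrics(conf)),
    }
    return report


def _stage_stats(cohort: Cohort, cfg: PipelineConfig) -> dict:
    report: dict = {}
    # per-family association with the Bacteria domain
    chisq = {}
    for fam in FAMILIES:
        bact = [r.domain == "Bacteria" for r in cohort]
        has = [r.family_counts[fam] >= 1 for r in cohort]
        if all(bact) or not any(bact):
            chisq[fam] = {"statistic": None, "p_value": None}
            continue
        t = TwoByTwo.from_indicators(has, bact)
        res = chisq_association(t)
        chisq[fam] = {"statistic": res.statistic, "p_value": res.p_value}
    report["chisq_family_vs_bacteria"] = chisq

    # phi of each family's absence against PG absence (known status only)
    known = cohort.subset(lambda r: r.pg_status != "unknown")
    phi = {}
    for fam in FAMILIES:
        absent = [r.family_counts[fam] == 0 for r in known]
        pg_absent = [r.pg_status == "absent" for r in known]
        phi[fam] = phi_correlation(TwoByTwo.from_indicators(absent, pg_absent))
    report["phi_absence_vs_pg_absence"] = phi

    try:
        pca = absence_pca(cohort)
        report["pca"] = {
            "loadings": {
                var: [round(float(x), 6) for x in row]
                for var, row in pca.loadings.iterrows()
            },
            "explained_variance_ratio": [
                round(float(v), 6) for v in pca.explained_variance_ratio
            ],
            "dropped": pca.dropped,
        }
    except Exception as exc:
        report["pca"] = {"skipped": str(exc)}

    try:
        reg = pg_absence_regression(cohort)
        report["regression"] = {
            name: {
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "separated": r.separated,
            }
            for name, r in reg.per_predictor.items()
        }
        report["regression"]["hosmer_lemeshow_p"] = reg.hosmer_lemeshow_p
    except Exception as exc:
        report["regression"] = {"skipped": str(exc)}
    return report


def _character_states(cohort: Cohort, tree: Phylogeny, what: str, cfg: PipelineConfig):
    char = character_from_cohort(cohort, what, tree, cfg.rule)
    work_tree = tree
    if char.excluded_tips:
        keep = [lab for lab in tree.tip_labels if lab not in char.excluded_tips]
        work_tree = tree.prune_to(keep)
    return work_tree, char


def _stage_events(cohort: Cohort, tree: Phylogeny, cfg: PipelineConfig) -> dict:
    report = {}
    for what in cfg.characters:
        work_tree, char = _character_states(cohort, tree, what, cfg)
        assignment = ancestral_parsimony(work_tree, char.states, cfg.costs, character=what)
        events, counts = extract_events(assignment, work_tree)
        report[what] = {
            "total_cost": assignment.total_cost,
            "n_gain": counts["gain"],
            "n_loss": counts["loss"],
            "excluded_tips": char.excluded_tips,
            "events": [
                {"type": e.type, "parent": e.parent_id, "child": e.child_id}
                for e in events
            ],
        }
    return report


def _stage_pagel(cohort: Cohort, tree: Phylogeny, cfg: PipelineConfig) -> dict:
    from .correlated_evolution import pagel_test

    if len(cfg.characters) < 2:
        return {"skipped": "need two characters"}
    ca, cb = cfg.characters[0], cfg.characters[1]
    work_tree, char_a = _character_states(cohort, tree, ca, cfg)
    char_b = character_from_cohort(cohort, cb, work_tree, cfg.rule)
    if char_b.excluded_tips:
        work_tree = work_tree.prune_to(
            [lab for lab in work_tree.tip_labels if lab not in char_b.excluded_tips]
        )
    result = pagel_test(
        work_tree,
        {lab: char_a.states[lab] for lab in work_tree.tip_labels},
        {lab: char_b.states[lab] for lab in work_tree.tip_labels},
        n_sim=cfg.n_sim,
        seed=cfg.seed,
    )
    return {"trait_a": ca, "trait_b": cb, **result.as_dict()}


def _stage_clusters(cohort: Cohort, tree: Phylogeny, cfg: PipelineConfig) -> dict:
    # events must live on one shared tree: prune to tips with known states for
    # every character, then reconstruct each character on that topology
    excluded: set[str] = set()
    for what in cfg.characters:
        char = character_from_cohort(cohort, what, tree, cfg.rule)
        excluded |= set(char.excluded_tips)
    shared = tree
    if excluded:
        shared = tree.prune_to([lab for lab in tree.tip_labels if lab not in excluded])
    all_events = []
    for what in cfg.characters:
        char = character_from_cohort(cohort, what, shared, cfg.rule)
        assignment = ancestral_parsimony(shared, char.states, cfg.costs, character=what)
        events, _ = extract_events(assignment, shared)
        all_events.extend(events)
    report = cluster_by_date(all_events)
    report = verify_clusters(
        report, shared, cohort, n_sim=cfg.n_sim, seed=cfg.seed, rule=cfg.rule
    )
    rows = []
    for i, c in enumerate(report.clusters):
        rows.append(
            {
                "cluster": i + 1,
                "n_dates": c.n_dates,
                "members": sorted([list(m) for m in c.members]),
                "dates": sorted(c.dates),
                "supported": c.supported,
                "scores": {
                    f"{a}/{b}": {
                        "score": round(r.score, 4),
                        "error_percentage": r.error_percentage,
                    }
                    for (a, b), r in c.verification.items()
                },
                "note": c.note,
            }
        )
    return {
        "clusters": rows,
        "n_unclustered_events": len(report.unclustered),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the summary written to the manifest.

    Any stage failure raises :class:`PipelineError` naming the stage; reports
    of stages already completed remain on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(config.annotation_tsv)
    tree = read_newick(config.tree_newick) if config.tree_newick else None

    needs_tree = {"events", "pagel", "clusters"}
    summary: dict = {}
    for stage in config.stages:
        t0 = time.monotonic()
        log.info("stage %s: starting", stage)
        try:
            if stage == "classify":
                report = _stage_classify(cohort, config)
            elif stage == "stats":
                report = _stage_stats(cohort, config)
            elif stage in needs_tree:
                if tree is None:
                    raise ValueError("stage requires a tree (tree_newick not set)")
                if stage == "events":
                    report = _stage_events(cohort, tree, config)
                elif stage == "pagel":
                    report = _stage_pagel(cohort, tree, config)
                else:
                    report = _stage_clusters(cohort, tree, config)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        _dump(report, out / f"{stage}.json")
        summary[stage] = f"{stage}.json"
        log.info("stage %s: done in %.2fs", stage, time.monotonic() - t0)

    config_json = json.dumps(config.as_dict(), sort_keys=True)
    manifest = {
        "pgtrait_version": __version__,
        "python_version": sys.version.split()[0],
        "seed": config.seed,
        "config": config.as_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "n_genomes": len(cohort),
        "n_tree_tips": None if tree is None else tree.n_tips,
        "reports": summary,
    }
    _dump(manifest, out / "manifest.json")
    return manifest
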