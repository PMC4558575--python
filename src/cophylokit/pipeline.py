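"""End-to-end cophylogenetic analysis pipeline.

Orchestrates the stages in dependency order: species delimitation from
an alignment, tree preprocessing (support collapsing, terminal
single-host clade collapsing), event-based reconciliation with adaptive
cost estimation, the topological-congruence randomization test, the
distance-based ParaFit test, the diversification rate-shift test, and
molecular-rate calibration.  The configuration carries one master seed
that fans out to per-stage seeds by fixed offsets, so a run is fully
reproducible from its config echo.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .congruence import parafit_links
from .delimit import (
    DelimitationConfig,
    DistanceModel,
    collapse_haplotypes,
    calibrate_rate,
    delimit_species,
    distance_matrix,
    read_fasta_alignment,
)
from .diversification import branching_times, ltt, rate_shift_test
from .reconcile import (
    ReconciliationOptions,
    check_chronology,
    cospeciation_significance,
    estimate_costs,
    flag_implausible,
)
from .trees import (
    collapse_low_support,
    collapse_terminal_host_clades,
    patristic_distances,
    read_links,
    read_tree,
)

logger = logging.getLogger("cophylokit")

ALL_STAGES = (
    "delimitation",
    "reconciliation",
    "congruence",
    "diversification",
    "calibration",
)

# fixed per-stage seed offsets from the master seed
_SEED_OFFSETS = {
    "reconciliation": 101,
    "treemap": 202,
    "congruence": 303,
    "diversification": 404,
}


@dataclass
class PipelineConfig:
    """Inputs, thresholds and replication settings of one analysis run.

    Defaults follow the standard protocol for this kind of analysis:
    1% / 2% delimitation cut-offs for nuclear / mitochondrial markers,
    70% bootstrap support collapsing, 10^4 cost sets, 10^4 random trees
    for the congruence randomization, 9999 ParaFit permutations, 5000
    null trees for the rate-shift test, and a 2.4 My root calibration.
    """

    host_tree: str | None = None
    parasite_tree: str | None = None
    links: str | None = None
    alignment: str | None = None
    ultrametric_tree: str | None = None
    host_distances: str | None = None
    parasite_distances: str | None = None

    marker: str = "ITS"  # "ITS" (nuclear) or "COI" (mitochondrial)
    theta_its: float = 0.01
    theta_coi: float = 0.02
    support_collapse: float = 70.0
    collapse_terminal: bool = True
    gamma_shape_its: float = 0.40
    gamma_shape_coi: float = 0.11

    root_to_root: bool = True
    charge_dup_with_switch: bool = False
    allow_polytomies: bool = True

    n_cost_sets: int = 10000
    n_rand_treemap: int = 10000
    n_perm_parafit: int = 9999
    n_null_trees: int = 5000

    calibration_divergence: tuple[float, float] = (2.0, 7.0)  # percent
    calibration_age: float = 2.4  # Mya

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "calibration_divergence" in raw:
            raw["calibration_divergence"] = tuple(raw["calibration_divergence"])
        return cls(**raw)

    def validate(self) -> list[str]:
        problems = []
        for theta, name in ((self.theta_its, "theta_its"), (self.theta_coi, "theta_coi")):
            if not 0 < theta < 1:
                problems.append(f"{name} must lie in (0, 1), got {theta}")
        for count in ("n_cost_sets", "n_rand_treemap", "n_perm_parafit", "n_null_trees"):
            if getattr(self, count) < 1:
                problems.append(f"{count} must be >= 1")
        if self.calibration_age <= 0:
            problems.append("calibration_age must be positive")
        if self.marker not in ("ITS", "COI"):
            problems.append(f"marker must be ITS or COI, got {self.marker!r}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            problems.append(f"unknown stages: {sorted(unknown)}")
        for stage, paths in {
            "delimitation": [self.alignment],
            "reconciliation": [self.host_tree, self.parasite_tree, self.links],
            "congruence": [self.host_tree, self.parasite_tree, self.links],
            "diversification": [self.ultrametric_tree],
        }.items():
            if stage in self.stages:
                for p in paths:
                    if p is None:
                        problems.append(f"stage {stage} needs an input path")
                    elif not Path(p).exists():
                        problems.append(f"stage {stage}: missing file {p}")
        return problems

    @property
    def theta(self) -> float:
        return self.theta_its if self.marker == "ITS" else self.theta_coi

    @property
    def gamma_shape(self) -> float:
        return self.gamma_shape_its if self.marker == "ITS" else self.gamma_shape_coi


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


def _preflight(config: PipelineConfig):
    problems = config.validate()
    host = parasite = links = None
    if {"reconciliation", "congruence"} & set(config.stages) and not problems:
        host = read_tree(config.host_tree)
        parasite = read_tree(config.parasite_tree)
        links = read_links(config.links)
        host_leaves = set(host.leaf_labels())
        par_leaves = set(parasite.leaf_labels())
        for p in links.parasite_labels:
            if p not in par_leaves:
                problems.append(f"linked parasite {p!r} absent from parasite tree")
        for h in links.host_labels:
            if h not in host_leaves:
                problems.append(f"linked host {h!r} absent from host tree")
        for leaf in par_leaves:
            if leaf not in links.parasite_labels:
                problems.append(f"parasite leaf {leaf!r} has no link")
    if problems:
        raise PipelineError("pre-flight validation failed:\n- " + "\n- ".join(problems))
    return host, parasite, links


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return a machine-readable report."""
    host, parasite, links = _preflight(config)
    report: dict = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }

    def stage(name):
        return name in config.stages

    t0 = time.perf_counter()

    if stage("delimitation"):
        logger.info("[delimitation] starting")
        aln = read_fasta_alignment(config.alignment)
        haps = collapse_haplotypes(aln)
        model = DistanceModel("JC+G", alpha=config.gamma_shape)
        D = distance_matrix(haps.to_alignment(), model)
        n_species, assignment = delimit_species(
            D, DelimitationConfig(threshold=config.theta)
        )
        from .delimit import alignment_stats

        length, n_var, n_pi = alignment_stats(aln)
        report["stages"]["delimitation"] = {
            "marker": config.marker,
            "alignment_length": length,
            "n_sequences": aln.n_sequences,
            "n_variable": n_var,
            "n_parsimony_informative": n_pi,
            "n_haplotypes": haps.n_haplotypes,
            "threshold": config.theta,
            "n_species": n_species,
            "clusters": assignment,
        }

    if stage("reconciliation"):
        logger.info("[reconciliation] starting")
        par_work, links_work = parasite, links
        if config.support_collapse > 0:
            par_work = collapse_low_support(par_work, config.support_collapse)
        if config.collapse_terminal:
            par_work, links_work = collapse_terminal_host_clades(par_work, links_work)
        opts = ReconciliationOptions(
            root_to_root=config.root_to_root,
            charge_dup_with_switch=config.charge_dup_with_switch,
            allow_polytomies=config.allow_polytomies,
        )
        scheme, rec, quality, ranked = estimate_costs(
            host,
            par_work,
            links_work,
            n_sets=config.n_cost_sets,
            seed=config.seed + _SEED_OFFSETS["reconciliation"],
            opts=opts,
        )
        flagged, reason = flag_implausible(rec, scheme)
        retained = rec
        if flagged:
            report["warnings"].append(f"best reconciliation rejected: {reason}")
            for cand in ranked[1:]:
                ok, _ = flag_implausible(cand, cand.costs)
                if not ok:
                    retained = cand
                    break
        observed, p_cosp = cospeciation_significance(
            host,
            par_work,
            links_work,
            n_rand=config.n_rand_treemap,
            seed=config.seed + _SEED_OFFSETS["treemap"],
            opts=opts,
        )
        report["stages"]["reconciliation"] = {
            "solutions": [r.summary_row() for r in ranked],
            "retained": retained.to_dict(),
            "plausibility": {"flagged": flagged, "reason": reason},
            "chronology_consistent": check_chronology(host, retained),
            "congruence_randomization": {
                "max_cospeciations": observed,
                "n_random_trees": config.n_rand_treemap,
                "p": p_cosp,
            },
        }

    if stage("congruence"):
        logger.info("[congruence] starting")
        host_D = (
            patristic_distances(host)
            if config.host_distances is None
            else _read_distances(config.host_distances)
        )
        par_D = (
            patristic_distances(parasite)
            if config.parasite_distances is None
            else _read_distances(config.parasite_distances)
        )
        res = parafit_links(
            host_D,
            par_D,
            links,
            n_perm=config.n_perm_parafit,
            seed=config.seed + _SEED_OFFSETS["congruence"],
        )
        report["stages"]["congruence"] = {
            "global_stat": res.global_stat,
            "global_p": res.global_p,
            "n_permutations": res.n_permutations,
            "n_links": len(res.link_labels),
            "n_significant_links": res.n_significant_links(0.05),
            "links": res.links_frame().to_dict(orient="records"),
        }

    if stage("diversification"):
        logger.info("[diversification] starting")
        tree = read_tree(config.ultrametric_tree)
        times = branching_times(tree)
        test = rate_shift_test(
            times,
            n_null=config.n_null_trees,
            seed=config.seed + _SEED_OFFSETS["diversification"],
        )
        report["stages"]["diversification"] = {
            "n_tips": times.n_tips,
            "ltt": ltt(times),
            "fits": [
                {"model": f.model, "params": f.params, "logL": f.logL, "AIC": f.AIC}
                for f in test.fits
            ],
            "delta_aic_rc": test.delta_aic_rc,
            "p": test.p,
            "n_null": test.n_null,
        }

    if stage("calibration"):
        d_lo, d_hi = config.calibration_divergence
        rate_lo, rate_hi = calibrate_rate(d_lo, d_hi, config.calibration_age)
        report["stages"]["calibration"] = {
            "divergence_percent": [d_lo, d_hi],
            "age_mya": config.calibration_age,
            "rate_percent_per_my": [rate_lo, rate_hi],
        }

    logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    return report


def _read_distances(path):
    from .trees import DistanceMatrix

    return DistanceMatrix.from_tsv(path)
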