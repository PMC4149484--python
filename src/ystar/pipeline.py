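"""End-to-end orchestration: simulate -> call -> tree -> date -> stars.

A run is fully determined by its :class:`RunConfig` plus any input files;
every output file carries a provenance header with the package version,
a hash of the configuration and the master seed, and reruns are
byte-identical. Per-stage seeds are derived deterministically from the
master seed, so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import calls as calls_mod
from . import clock as clock_mod
from . import expansions as exp_mod
from . import simulate as sim_mod
from . import tree as tree_mod
from .matrices import AlleleCountMatrix

__all__ = [
    "RunConfig",
    "PipelineError",
    "AnalysisResult",
    "impute_with_guide",
    "run_analysis",
    "run",
    "make_fixtures",
]


class PipelineError(RuntimeError):
    """A stage's inputs are missing or inconsistent."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int = 1
    simulate: bool = True
    scenario: str = "demo"  # demo | star | binary
    star_specs: tuple = ((10, 5_400.0), (10, 6_500.0), (10, 6_800.0))
    n_background: int = 19
    n_tips: int = 49  # binary scenario size
    root_age_years: float = 54_100.0
    seq: sim_mod.SeqParams = field(default_factory=sim_mod.SeqParams)
    policy: calls_mod.SiteFilterPolicy = field(default_factory=calls_mod.SiteFilterPolicy)
    clock: clock_mod.ClockModel = field(default_factory=clock_mod.ClockModel)
    min_lineages: int = 5
    max_window_years: float = 1_000.0
    haplogroup_letter: str = "O"
    ci_method: str = "normal"
    conf: float = 0.95
    date_tier: str = "any"  # any | good
    counts_path: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class AnalysisResult:
    calls_raw: object
    calls_filtered: object
    calls_imputed: object
    genealogy: tree_mod.Genealogy
    ages: dict
    collapsed: tree_mod.Genealogy
    stars: list
    report: dict


def _scenario_for(config: RunConfig) -> sim_mod.Scenario:
    if config.scenario == "demo":
        return sim_mod.multi_star_scenario(
            star_specs=config.star_specs,
            n_background=config.n_background,
            root_age_years=config.root_age_years,
            seed=config.seed,
        )
    if config.scenario == "star":
        k, age = config.star_specs[0]
        return sim_mod.star_scenario(k, age, config.root_age_years)
    if config.scenario == "binary":
        return sim_mod.binary_scenario(
            config.n_tips, config.root_age_years, seed=config.seed
        )
    raise PipelineError(f"unknown scenario {config.scenario!r}")


def _guide_tree(cm) -> tree_mod.Genealogy:
    """Provisional topology for imputation, from unambiguous columns only.

    A column with a missing cell cannot distinguish a clade from the same
    clade minus the missing sample, so using such columns for the guide
    tree plants spurious nested splits; complete columns carry the same
    clades without that artifact. Falls back to treating missing cells as
    ancestral when no column is complete.
    """
    complete = ~np.isin(cm.states, list("?-")).any(axis=0)
    if complete.any():
        return tree_mod.build_tree(cm.subset_sites(complete))
    return tree_mod.build_tree(cm, missing_as_ancestral=True)


def impute_with_guide(cm, seed: int):
    """Impute a call matrix on a tree inferred from the matrix itself.

    Two stages: a provisional guide from the unambiguous columns resolves
    most cells; rebuilding the tree from that first pass recovers sparsely
    supported edges the provisional guide missed, and the original matrix
    is re-imputed on the refined topology. Returns (imputed matrix, tree).
    """
    guide = _guide_tree(cm)
    first = calls_mod.impute_missing(cm, guide, seed=seed)
    refined = tree_mod.build_tree(first)
    final = calls_mod.impute_missing(cm, refined, seed=seed)
    return final, refined


def run_analysis(
    counts: AlleleCountMatrix, config: RunConfig | None = None
) -> AnalysisResult:
    """Run calling, tree building, dating and star detection in memory."""
    if config is None:
        config = RunConfig()
    policy, clk = config.policy, config.clock

    cm = calls_mod.call_matrix(counts, policy)
    cm = calls_mod.apply_private_filter(cm, counts, policy)
    cmf = calls_mod.filter_sites(cm, policy)
    if cmf.n_sites == 0:
        raise PipelineError("no site passed the coverage filter")

    cmi, _ = impute_with_guide(cmf, seed=config.seed)
    genealogy = tree_mod.build_tree(cmi)

    date_tips = None
    if config.date_tier == "good":
        depths = counts.mean_depths()
        date_tips = {
            s
            for s, d in zip(counts.samples, depths)
            if calls_mod.quality_tier(float(d)) == "good"
        }
        if not date_tips:
            raise PipelineError("no good-tier sample available for dating")
    ages = clock_mod.date_tree(
        genealogy, clk, conf=config.conf, method=config.ci_method, tips=date_tips
    )

    collapsed = exp_mod.collapse_short_branches(genealogy, clk, config.max_window_years)
    clock_mod.date_tree(collapsed, clk, conf=config.conf, method=config.ci_method)
    stars = exp_mod.detect_stars(
        collapsed,
        clk,
        min_lineages=config.min_lineages,
        max_window_years=config.max_window_years,
        conf=config.conf,
    )
    stars = exp_mod.assign_names(stars, config.haplogroup_letter)

    rtt = [genealogy.branch_counts(t) for t in genealogy.tip_names]
    disp = clock_mod.clock_dispersion_test(rtt) if np.mean(rtt) > 0 else None
    report = {
        "n_samples": counts.n_samples,
        "n_sites_raw": counts.n_sites,
        "n_sites_filtered": cmf.n_sites,
        "n_conflicts": len(genealogy.conflicts),
        "n_stars": len(stars),
        "mean_root_to_tip": float(np.mean(rtt)),
        "dispersion_p": disp.pvalue if disp else None,
        "dispersion_note": "Poisson index-of-dispersion stand-in for a "
        "likelihood-ratio clock test",
    }
    return AnalysisResult(cm, cmf, cmi, genealogy, ages, collapsed, stars, report)


def _header_meta(config: RunConfig) -> dict:
    return {
        "ystar_version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
    }


def run(config: RunConfig, outdir) -> dict:
    """Execute the enabled stages and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = _header_meta(config)

    if config.simulate:
        scenario = _scenario_for(config)
        params = config.seq.with_seed(config.seed)
        mut = sim_mod.simulate_mutations(scenario, params)
        counts = sim_mod.simulate_reads(mut, params)
        counts.meta.update(meta)
        counts.to_tsv(outdir / "allele_counts.tsv")
    elif config.counts_path:
        counts = AlleleCountMatrix.from_tsv(config.counts_path)
    else:
        raise PipelineError(
            "simulation disabled and no counts_path given: enable the "
            "simulate stage or point counts_path at an allele-count TSV"
        )

    res = run_analysis(counts, config)
    res.calls_imputed.meta.update(meta)
    res.calls_imputed.to_tsv(outdir / "calls.tsv")
    calls_mod.write_pseudo_fasta(res.calls_imputed, outdir / "pseudo.fasta")

    # provenance as a leading Newick comment (legal, skipped by parsers)
    nwk_meta = (
        f"[&ystar_version={meta['ystar_version']},"
        f"config_hash={meta['config_hash']},seed={meta['seed']}]\n"
    )
    (outdir / "tree.nwk").write_text(
        nwk_meta + res.genealogy.to_newick(lengths="count") + "\n"
    )
    (outdir / "tree_dated.nwk").write_text(
        nwk_meta + res.genealogy.to_newick(lengths="count", annotate_ages=True) + "\n"
    )
    tsv_meta = "".join(f"# {k}={meta[k]}\n" for k in sorted(meta))
    with open(outdir / "site_branches.tsv", "w") as fh:
        fh.write(tsv_meta + "site\tbranch\n")
        for node in res.genealogy.preorder():
            for site in node.edge_sites:
                fh.write(f"{site + 1}\t{node.name}\n")
    with open(outdir / "conflicts.tsv", "w") as fh:
        fh.write(tsv_meta + "site\tconflicts_with\n")
        for site, other in res.genealogy.conflicts:
            fh.write(f"{site + 1}\t{other + 1}\n")

    star_rows = [
        {
            "name": s.name,
            "node": s.node,
            "lineages": s.lineage_count,
            "tips": s.n_tips,
            "age_years": round(s.age.point, 1) if s.age else None,
            "ci_low": round(s.age.ci_low, 1) if s.age else None,
            "ci_high": round(s.age.ci_high, 1) if s.age else None,
            "window_upper_years": round(s.window_years, 1),
        }
        for s in res.stars
    ]
    (outdir / "stars.json").write_text(
        json.dumps({"meta": meta, "stars": star_rows}, indent=2, sort_keys=True)
        + "\n"
    )

    report = {"meta": meta, "config": config.to_dict(), **res.report}
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
    )
    return report


def make_fixtures(seed: int = 0, outdir="fixtures") -> dict:
    """Write the small toy dataset used by examples and tests.

    Contents: a toy two-chromosome genome with a planted 500-bp duplication
    and a 230-bp unique island for the bait designer; a star and a binary
    scenario as Newick (year branch lengths); a small simulated
    allele-count matrix.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([seed, 7])
    bases = np.array(list("ACGT"))

    def rand_seq(n):
        return "".join(rng.choice(bases, size=n))

    target = rand_seq(3_000)
    dup = target[1_000:1_500]
    decoy = rand_seq(1_200) + dup + rand_seq(1_300)
    genome = {"chrT": target, "chrD": decoy}
    with open(outdir / "bait_genome.fasta", "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")

    star = sim_mod.star_scenario(10, 5_400.0, 54_100.0)
    (outdir / "star_scenario.nwk").write_text(
        star.genealogy.to_newick(lengths="years") + "\n"
    )
    binary = sim_mod.binary_scenario(12, 54_100.0, seed=seed)
    (outdir / "binary_scenario.nwk").write_text(
        binary.genealogy.to_newick(lengths="years") + "\n"
    )

    params = sim_mod.SeqParams(seed=seed)
    mut = sim_mod.simulate_mutations(binary, params)
    counts = sim_mod.simulate_reads(mut, params)
    counts.meta["seed"] = seed
    counts.to_tsv(outdir / "allele_counts.tsv")
    return {
        "genome": str(outdir / "bait_genome.fasta"),
        "star": str(outdir / "star_scenario.nwk"),
        "binary": str(outdir / "binary_scenario.nwk"),
        "counts": str(outdir / "allele_counts.tsv"),
        "seed": seed,
    }
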