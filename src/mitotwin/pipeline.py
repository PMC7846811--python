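"""End-to-end orchestration: simulate -> partition -> QC -> dating -> trees.

Runs the whole desk-scale analysis on synthetic data that emulates the
two-molecule study system: a 1:7-ish minor:major long-read mixture is
binned against the two references, both molecules are QC'd as mitochondrial,
their divergence is clock-dated, population placement and non-coding-block
concerted evolution are tested by exact parsimony, and the gene orders are
compared.  Every stage is importable on its own; this module only composes
them and collects a JSON-serializable report.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import divergence as dv
from . import gene_order as go
from . import parsimony as mp
from . import partition as pt
from . import qc
from .io import MitoGenome, MultipleAlignment, ValidationError
from .simulate import (
    SimConfig,
    evolve_lineage,
    mix_reads,
    simulate_long_reads,
    simulate_truth_set,
)

_ALL_STAGES = ("simulate", "partition", "qc", "divergence", "phylo",
               "nc_phylo", "gene_order")


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple[str, ...] = _ALL_STAGES
    delta: float = 0.05
    min_len: int = 500
    clock_rate: float = 1.3
    bootstrap_reps: int = 100
    # long-read pool sizes for the mixture experiment (desk-scale)
    n_long_major: int = 260
    n_long_minor: int = 60
    # population structure around M1 (proportions of sites):
    # the northern ancestor and the population root are placed on the
    # M1 lineage by reverting nested subsets of M1's derived changes, so
    # the second molecule attaches between the two island groups
    north_depth: float = 0.004
    root_depth: float = 0.008
    south_divergence: float = 0.008
    tip_divergence: float = 0.002
    n_north: int = 2
    n_south: int = 2
    # third, southern-type sample used in the non-coding-block analysis
    si_divergence: float = 0.02

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in data and isinstance(data["sim"], dict):
            sim_known = set(SimConfig.__dataclass_fields__)
            sim_unknown = set(data["sim"]) - sim_known
            if sim_unknown:
                raise ValidationError(
                    f"unknown sim config keys: {sorted(sim_unknown)}")
            data["sim"] = SimConfig(**data["sim"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _revert_positions(derived: MitoGenome, ancestor: MitoGenome,
                      positions: np.ndarray, label: str) -> MitoGenome:
    seq = list(derived.sequence)
    anc = ancestor.sequence
    for p in positions:
        seq[int(p)] = anc[int(p)]
    return MitoGenome(label, "".join(seq), True, list(derived.annotations),
                      molecule_tag=derived.molecule_tag)


def _population(truth, config: PipelineConfig) -> dict[str, MitoGenome]:
    """LAI M1/M2 plus northern and southern island samples.

    The population root (where the second molecule attaches) and the
    northern ancestor are intermediate points on the M1 lineage, built by
    reverting nested random subsets of M1's derived sites back to the
    ancestral state; island samples then evolve forward from those points.
    The LAI M1 genome itself sits inside the northern group, carrying the
    reverted sites as its own derived characters.
    """
    seed = config.sim.seed
    m1, m2, anc = truth.genome_m1, truth.genome_m2, truth.ancestor
    L = len(m1)
    a = np.frombuffer(anc.sequence.encode(), dtype=np.uint8)
    b = np.frombuffer(m1.sequence.encode(), dtype=np.uint8)
    derived_sites = np.where(a != b)[0]
    rng = np.random.default_rng([seed % (2**31), 601])
    n_root = min(len(derived_sites), int(round(config.root_depth * L)))
    n_north = min(n_root, int(round(config.north_depth * L)))
    root_sites = rng.choice(derived_sites, size=n_root, replace=False)
    north_sites = rng.choice(root_sites, size=n_north, replace=False)
    north_anc = _revert_positions(m1, anc, north_sites, "north_anc")
    pop_root = _revert_positions(m1, anc, root_sites, "pop_root")
    south_anc = evolve_lineage(pop_root, config.south_divergence,
                               seed + 301, "south_anc")
    genomes: dict[str, MitoGenome] = {"LAI_M1": m1, "LAI_M2": m2}
    for i in range(config.n_north):
        genomes[f"north{i + 1}"] = evolve_lineage(
            north_anc, config.tip_divergence, seed + 310 + i, f"north{i + 1}")
    for i in range(config.n_south):
        genomes[f"south{i + 1}"] = evolve_lineage(
            south_anc, config.tip_divergence, seed + 330 + i, f"south{i + 1}")
    return genomes


def _splits_as_strings(d: dict) -> dict:
    return {"|".join(sorted(k)): round(v, 2) for k, v in d.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns a self-contained report dict; deterministic given the config
    (wall-clock fields aside).
    """
    report: dict = {"config": {"sim": asdict(config.sim),
                               "stages": list(config.stages)},
                    "stages": {}}
    t_start = time.time()
    want = set(config.stages)
    if not want:
        return report

    truth = simulate_truth_set(config.sim)
    genomes = {"M1": truth.genome_m1, "M2": truth.genome_m2}

    if "simulate" in want:
        report["stages"]["simulate"] = {
            "genome_length_m1": len(truth.genome_m1),
            "genome_length_m2": len(truth.genome_m2),
            "realized_divergence": truth.realized_divergence,
        }

    table = None
    if "partition" in want:
        reads_m1 = simulate_long_reads(truth.genome_m1, config.sim,
                                       n_reads=config.n_long_major, prefix="m1_")
        reads_m2 = simulate_long_reads(truth.genome_m2, config.sim,
                                       n_reads=config.n_long_minor, prefix="m2_")
        mixture = mix_reads(reads_m1, reads_m2, config.sim.minor_fraction,
                            config.sim.seed)
        table = pt.assign_reads(mixture, truth.genome_m1, truth.genome_m2,
                                delta=config.delta, min_len=config.min_len)
        est = pt.mixture_fraction(table)
        called = [r for r in table if r.call in ("M1", "M2")]
        correct = sum(1 for r in called if r.call == r.true_origin)
        cov1 = pt.coverage_summary(table, truth.genome_m1, "M1")
        cov2 = pt.coverage_summary(table, truth.genome_m2, "M2")
        report["stages"]["partition"] = {
            "n_reads": len(mixture),
            "counts": dict(table.counts()),
            "assignment_accuracy": correct / len(called) if called else None,
            "minor_fraction": est.minor_fraction,
            "minor_fraction_ci": [est.ci_low, est.ci_high],
            "coverage_m1": cov1.as_dict(),
            "coverage_m2": cov2.as_dict(),
        }

    if "qc" in want:
        out = {}
        for name, g in genomes.items():
            comp = qc.base_composition(g)
            trans = qc.translate_cds(g)
            trnas = [a for a in g.annotations if a.kind == "tRNA"]
            folded = sum(
                qc.fold_trna(g.feature_sequence(a)).folded for a in trnas)
            out[name] = {
                "guanine_pct_heavy": round(comp.guanine_pct_heavy, 1),
                "translation_pass": trans.passed,
                "n_cds": len(trans.per_cds),
                "trnas_folded": folded,
                "n_trnas": len(trnas),
            }
        report["stages"]["qc"] = out

    if "divergence" in want or "phylo" in want:
        population = _population(truth, config)

    if "divergence" in want:
        aln = MultipleAlignment(
            names=list(population.keys()),
            rows=[g.sequence for g in population.values()],
        )
        d12 = dv.pairwise_p_distance(aln, "LAI_M1", "LAI_M2")
        north = [n for n in population if n.startswith("north")]
        south = [n for n in population if n.startswith("south")]
        d_ns = dv.mean_group_divergence(aln, north, south)
        d_m2 = dv.mean_group_divergence(
            aln, north + south + ["LAI_M1"], ["LAI_M2"])
        report["stages"]["divergence"] = {
            "d_m1_m2": d12.d,
            "date_m1_m2_my": dv.clock_date(d12.d, config.clock_rate).time_my_rounded,
            "d_north_south": d_ns,
            "date_north_south_my": dv.clock_date(d_ns, config.clock_rate).time_my_rounded,
            "d_all_m1_vs_m2": d_m2,
        }

    if "phylo" in want:
        gene_set = [a.name for a in truth.genome_m1.annotations
                    if a.kind == "CDS"]
        aln, _ = mp.build_concatenation(population, gene_set)
        res = mp.branch_and_bound_search(aln)
        support = mp.bootstrap(aln, replicates=config.bootstrap_reps,
                               seed=config.sim.seed + 401)
        consensus = mp.strict_consensus(res.shortest_trees)
        decay = {
            s: mp.decay_index(aln, s, unconstrained=res)
            for s in consensus.splits()
        }
        free, constrained, temp, diff = mp.test_monophyly(
            aln, ["LAI_M1", "LAI_M2"])
        report["stages"]["phylo"] = {
            "n_sites": res.n_sites,
            "n_informative": res.n_parsimony_informative,
            "length": res.length,
            "n_shortest_trees": len(res.shortest_trees),
            "consensus_newick": consensus.newick(),
            "bootstrap": _splits_as_strings(support),
            "decay": _splits_as_strings(decay),
            "whole_tree_collapse": min(decay.values()) if decay else 0,
            "lai_monophyly_extra_steps": diff,
            "lai_monophyly_p": temp.p_two_tailed,
        }

    if "nc_phylo" in want:
        from .simulate import rehomogenize_nc

        # the third sample splits from the M1 lineage half its divergence
        # back (reversion toward the ancestor), then evolves forward and
        # keeps homogenizing its own NC blocks — both lineages therefore
        # carry private shared-derived states across their block copies
        m1, anc = truth.genome_m1, truth.ancestor
        a = np.frombuffer(anc.sequence.encode(), dtype=np.uint8)
        b = np.frombuffer(m1.sequence.encode(), dtype=np.uint8)
        derived_sites = np.where(a != b)[0]
        rng = np.random.default_rng([config.sim.seed % (2**31), 701])
        n_back = min(len(derived_sites),
                     int(round(0.5 * config.si_divergence * len(m1))))
        back = rng.choice(derived_sites, size=n_back, replace=False)
        si_base = _revert_positions(m1, anc, back, "si_base")
        third = rehomogenize_nc(
            evolve_lineage(si_base, 0.5 * config.si_divergence,
                           config.sim.seed + 501, "SI"),
            nc_within_identity=config.sim.nc_within_identity,
            kappa=config.sim.kappa, seed=config.sim.seed + 511)
        nc_names, nc_rows = [], []
        for gname, g in (("M1", truth.genome_m1), ("M2", truth.genome_m2),
                         ("SI", third)):
            for a in g.annotations:
                if a.kind == "NC":
                    nc_names.append(f"{gname}_{a.name}")
                    nc_rows.append(g.feature_sequence(a))
        width = min(len(r) for r in nc_rows)
        aln = MultipleAlignment(names=nc_names,
                                rows=[r[:width] for r in nc_rows])
        res = mp.branch_and_bound_search(aln)
        consensus = mp.strict_consensus(res.shortest_trees)
        by_genome = {
            g: [n for n in nc_names if n.startswith(g + "_")]
            for g in ("M1", "M2", "SI")
        }
        clustering = {g: consensus.has_clade(v) for g, v in by_genome.items()}
        block_tests = {}
        for blk in ("NC1", "NC2", "NC3"):
            group = [n for n in nc_names if n.endswith(blk)]
            _, _, temp, diff = mp.test_monophyly(aln, group)
            block_tests[blk] = {"extra_steps": diff, "p": temp.p_two_tailed}
        report["stages"]["nc_phylo"] = {
            "n_sites": res.n_sites,
            "n_informative": res.n_parsimony_informative,
            "length": res.length,
            "n_shortest_trees": len(res.shortest_trees),
            "consensus_newick": consensus.newick(),
            "blocks_cluster_by_genome": clustering,
            "block_monophyly_tests": block_tests,
        }

    if "gene_order" in want:
        rep = go.compare_orders(go.TUATARA, go.STANDARD_VERTEBRATE)
        anc_order = go.extract_order(truth.ancestor)
        std_names = [g.name for g in go.STANDARD_VERTEBRATE.genes
                     if g.kind != "NC"]
        anc_names = [g.name for g in anc_order.genes if g.kind != "NC"]
        report["stages"]["gene_order"] = {
            "tuatara_vs_standard": {
                "moved_genes": rep.moved_genes,
                "duplicated_elements": rep.duplicated_elements,
                "extra_noncoding_blocks": rep.extra_noncoding_blocks,
                "breakpoint_count": rep.breakpoint_count,
            },
            "ancestor_order_is_standard": anc_names == std_names,
        }

    report["wall_clock_s"] = round(time.time() - t_start, 2)
    return report


# ---------------------------------------------------------------------------
# in-study analytic numbers recomputed from their printed inputs


def demo_paper_numbers() -> list[dict]:
    """Recompute each analytic quantity from its stated inputs.

    The read counts, divergences and site tallies are inputs here (they are
    printed observables); the arithmetic is the package's.
    """
    rows = []
    est = pt.mixture_fraction(176_980, 30_005)
    rows.append({
        "quantity": "minor-molecule share of assignable reads",
        "inputs": "176,980 M1 + 30,005 M2",
        "expected": 14.5,
        "computed": round(100.0 * est.minor_fraction, 1),
    })
    rows.append({
        "quantity": "assignable reads",
        "inputs": "176,980 + 30,005",
        "expected": 206_985,
        "computed": est.n_assignable,
    })
    rows.append({
        "quantity": "M1-M2 separation (My)",
        "inputs": "10.1% at 1.3%/My",
        "expected": 7.8,
        "computed": dv.clock_date(0.101, 1.3).time_my_rounded,
    })
    rows.append({
        "quantity": "north-south separation (My)",
        "inputs": "1.6% at 1.3%/My",
        "expected": 1.2,
        "computed": dv.clock_date(0.016, 1.3).time_my_rounded,
    })
    table = (
        [(i, "transmembrane", True) for i in range(43)]
        + [(i + 43, "loop", True) for i in range(12)]
        + [(i + 55, "loop", False) for i in range(45)]
    )
    summary = qc.site_class_fraction(table)
    rows.append({
        "quantity": "positively selected sites in transmembrane regions (%)",
        "inputs": "43 of 55 flagged sites",
        "expected": 78,
        "computed": summary.per_class_pct_of_flagged["transmembrane"],
    })
    return rows
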