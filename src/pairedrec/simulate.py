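"""Forward simulator of a tandem paired-receptor gene cluster.

Generates chromosome FASTA, GFF3 gene models, per-gene N-exon FASTA and
a machine-readable truth table for a gene family with the statistical
structure the analysis pipeline assumes:

* two anciently diverged subgroups of tandem paralogs on one chromosome;
* genes with leader / N (IgV-like) / IgC / TM / cytoplasmic exons and
  canonical GT..AG introns;
* codon evolution with a per-codon omega profile -- background purifying
  selection, with diversifying selection (omega > 1) confined to the
  beta-strand windows of the N domain on inhibitory-receptor lineages;
* a speciation event and, in one daughter species, an allotetraploid
  whole-locus duplication into L and S copies followed by heavy gene
  loss on S;
* recent gene-conversion events that copy an N-exon tract from the
  inhibitory donor into its activating partner(s), the mechanism that
  keeps paired-receptor ligand-binding domains alike;
* ITIM/ITSM or ITAM peptide cassettes in cytoplasmic exons, opposite
  transcriptional orientation of paired genes, and programmed
  pseudogenization by internal stops or corrupted splice sites.

Amino-acid changing substitutions are accepted with probability
proportional to the codon's omega; cytoplasmic exons evolve under
complete purifying selection (omega = 0) so signaling-motif content is
a property of the inserted cassette, not of mutational noise.  Time is
measured in millions of years (My); the synonymous substitution rate
converts branch durations to expected synonymous substitutions per
synonymous site.
"""

from __future__ import annotations


import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .annotation import Exon, GeneModel
from .codon import BASES, GENETIC_CODE, SENSE_CODONS, STOP_CODONS
from . import io as prio

__all__ = [
    "SimConfig",
    "SubgroupConfig",
    "ConversionEvent",
    "PseudogeneEvent",
    "FamilyTruth",
    "SimulatedLocus",
    "SimulationResult",
    "random_coding_sequence",
    "evolve_codon_sequence",
    "evolve_nucleotide_sequence",
    "apply_conversion",
    "simulate_family",
    "encode_peptide",
    "ITIM_CASSETTE",
    "ITAM_CASSETTE",
]

# Deterministic reverse translation: first codon (sorted) per amino acid.
CODON_FOR_AA: dict[str, str] = {}
for _codon in SENSE_CODONS:
    CODON_FOR_AA.setdefault(GENETIC_CODE[_codon], _codon)

#: cytoplasmic cassette peptides; the ITIM cassette carries one ITIM and
#: one ITSM at non-ITAM spacing, the ITAM cassette one canonical ITAM.
ITIM_CASSETTE = "GKSAVTYAQLNPGAQSTEYSSVRQ"
ITAM_CASSETTE = "GRDPYQELAGSDDEAYSVIKSRE"


def encode_peptide(peptide: str) -> str:
    """Reverse-translate a peptide with a fixed codon per amino acid."""
    return "".join(CODON_FOR_AA[aa] for aa in peptide)


def random_coding_sequence(
    n_codons: int,
    rng: np.random.Generator,
    exclude_aas: str = "",
) -> str:
    """Random sense-codon sequence, optionally excluding amino acids."""
    pool = [c for c in SENSE_CODONS if GENETIC_CODE[c] not in exclude_aas]
    idx = rng.integers(0, len(pool), size=n_codons)
    return "".join(pool[i] for i in idx)


def evolve_codon_sequence(
    seq: str,
    branch_length: float,
    omega,
    rng: np.random.Generator,
    kappa: float = 1.0,
    frozen_codons: frozenset[int] | set[int] = frozenset(),
) -> str:
    """Evolve a codon sequence along a branch.

    ``branch_length`` is the expected number of synonymous substitutions
    per synonymous site.  Single-nucleotide changes are proposed at that
    per-site rate (transitions weighted ``kappa``); synonymous proposals
    are always accepted, nonsynonymous ones with probability equal to
    the codon's omega, and proposals creating stop codons are rejected.
    ``omega`` may be a scalar or a per-codon array.
    """
    if branch_length < 0:
        raise ValueError("branch length must be >= 0")
    if len(seq) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    n_codons = len(seq) // 3
    om = np.broadcast_to(np.asarray(omega, dtype=float), (n_codons,))
    if (om < 0).any():
        raise ValueError("omega must be >= 0")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for c in codons:
        if c in STOP_CODONS:
            raise ValueError("internal stop codon in input sequence")
    n_events = rng.poisson(branch_length * len(seq))
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for _ in range(n_events):
        pos = int(rng.integers(0, len(seq)))
        ci, off = divmod(pos, 3)
        if ci in frozen_codons:
            continue
        codon = codons[ci]
        old = codon[off]
        alts = [b for b in BASES if b != old]
        if kappa != 1.0:
            w = np.array([kappa if b == transition[old] else 1.0 for b in alts])
            new_base = alts[int(rng.choice(3, p=w / w.sum()))]
        else:
            new_base = alts[int(rng.integers(0, 3))]
        mutant = codon[:off] + new_base + codon[off + 1 :]
        if mutant in STOP_CODONS:
            continue
        if GENETIC_CODE[mutant] != GENETIC_CODE[codon]:
            if rng.random() >= om[ci]:
                continue
        codons[ci] = mutant
    return "".join(codons)


def evolve_nucleotide_sequence(
    seq: str,
    subs_per_site: float,
    rng: np.random.Generator,
    frozen: frozenset[int] | set[int] = frozenset(),
) -> str:
    """Neutral nucleotide evolution (introns, intergenic DNA)."""
    if subs_per_site < 0:
        raise ValueError("substitution rate must be >= 0")
    chars = list(seq)
    free = [i for i in range(len(chars)) if i not in frozen]
    if not free:
        return seq
    n_events = rng.poisson(subs_per_site * len(free))
    for _ in range(n_events):
        i = free[int(rng.integers(0, len(free)))]
        old = chars[i]
        alts = [b for b in BASES if b != old]
        chars[i] = alts[int(rng.integers(0, 3))]
    return "".join(chars)


def apply_conversion(acceptor: str, donor: str, tract: tuple[int, int]) -> str:
    """Replace a codon tract of the acceptor with the donor's tract.

    ``tract`` is a 0-based half-open codon interval; both sequences must
    cover it.  A zero-length tract returns the acceptor unchanged.
    """
    s, e = tract
    if s < 0 or e > len(acceptor) // 3 or e > len(donor) // 3:
        raise ValueError("conversion tract outside exon")
    if e < s:
        raise ValueError("tract end before start")
    return acceptor[: 3 * s] + donor[3 * s : 3 * e] + acceptor[3 * e :]


# --- configuration ------------------------------------------------------------


@dataclass
class SubgroupConfig:
    """One subgroup of tandem paralogs."""

    n_genes: int
    prefix: str  # gene ids are prefix + 2-digit index
    inhibitory: int  # 1-based gene index carrying the ITIM cassette
    activating: list[int]  # gene indices carrying the ITAM cassette

    def gene_ids(self) -> list[str]:
        return [f"{self.prefix}{i:02d}" for i in range(1, self.n_genes + 1)]

    def gene_id(self, index: int) -> str:
        return f"{self.prefix}{index:02d}"


@dataclass
class ConversionEvent:
    donor: str  # base gene id
    acceptor: str
    species: str  # "A" | "B"
    locus: str  # "" for species A, "L"/"S" for species B
    tract: tuple[int, int]  # codon interval on the N exon
    time: float  # My before present


@dataclass
class PseudogeneEvent:
    gene: str
    species: str
    locus: str
    mechanism: str  # "internal_stop" | "splice_donor" | "splice_acceptor"


@dataclass
class SimConfig:
    """Parameters of the cluster simulation (times in My).

    The defaults encode the study scenario: two subgroups of 20 and 18
    ancestral genes, speciation 60 My ago, allotetraploidization of
    species B 40 My ago, recent gene conversions from the inhibitory
    donor onto its activating partner(s), and loss of >80% of the genes
    from the S locus.
    """

    group1: SubgroupConfig = field(
        default_factory=lambda: SubgroupConfig(20, "c1", inhibitory=5, activating=[6])
    )
    group2: SubgroupConfig = field(
        default_factory=lambda: SubgroupConfig(18, "c2", inhibitory=5, activating=[6])
    )
    # exon template (codons) and intron lengths (nt)
    leader_codons: int = 20
    n_codons: int = 107
    igc_codons: int = 90
    tm_codons: int = 40
    cyt_codons: int = 32
    cassette_offset: int = 4  # codon offset of the cassette in the cyt exon
    intron_lengths: tuple[int, ...] = (250, 300, 280, 220)
    spacer_mean: int = 700
    spacer_jitter: int = 200
    # rates
    syn_rate: float = 0.0033  # synonymous substitutions / syn site / My
    intron_rate_multiplier: float = 1.5
    omega_background: float = 0.2
    omega_selected: float = 2.0
    kappa: float = 1.0
    # beta-strand windows under diversifying selection (codon intervals
    # on the N domain, 0-based half-open): the CC'C''FG face
    selected_windows: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "C": (32, 41),
            "Cp": (44, 52),
            "Cpp": (55, 63),
            "F": (78, 88),
            "G": (91, 101),
        }
    )
    # gene-family history
    cherry_time: float = 200.0  # duplication joining each (inhibitory, activating) pair
    dup_step: float = 8.0  # spacing of the older tandem duplications
    subgroup_split_branch: float = 1.0  # extra syn subs/site between subgroup roots
    subgroup_split_omega: float = 0.8
    speciation_time: float = 60.0
    allotetraploid_time: float = 40.0
    recent_duplications: list[dict] = field(
        default_factory=lambda: [
            {"gene": "c206", "species": "A", "time": 10.0, "suffix": "x"}
        ]
    )
    conversions: list[ConversionEvent] = field(
        default_factory=lambda: [
            ConversionEvent("c105", "c106", "A", "", (25, 103), 5.0),
            ConversionEvent("c205", "c206", "A", "", (25, 103), 12.0),
            ConversionEvent("c205", "c206x", "A", "", (25, 103), 12.0),
            ConversionEvent("c105", "c106", "B", "L", (25, 103), 5.0),
            ConversionEvent("c205", "c206", "B", "L", (25, 103), 5.0),
        ]
    )
    s_retained: list[str] = field(
        default_factory=lambda: ["c103", "c205", "c210", "c212"]
    )
    pseudogenes: list[PseudogeneEvent] = field(
        default_factory=lambda: [
            PseudogeneEvent("c108", "A", "", "internal_stop"),
            PseudogeneEvent("c112", "A", "", "splice_donor"),
        ]
    )
    anchoring_overrides: dict[str, str] = field(
        default_factory=lambda: {"c210": "GPI", "c212": "GPI", "c103": "secreted"}
    )

    def __post_init__(self) -> None:
        if self.cherry_time <= self.speciation_time:
            raise ValueError("paired-receptor duplication must predate speciation")
        if self.speciation_time <= self.allotetraploid_time:
            raise ValueError("allotetraploidization must postdate speciation")
        for ev in self.conversions:
            s, e = ev.tract
            if not (0 <= s < e <= self.n_codons):
                raise ValueError("conversion tract outside the N exon")
            if ev.time >= self.allotetraploid_time and ev.locus:
                raise ValueError("locus-specific conversion predates the L/S split")
        for dup in self.recent_duplications:
            if dup["time"] >= self.speciation_time:
                raise ValueError("recent duplication predates speciation")
        retained_set = set(self.s_retained)
        known = set(self.group1.gene_ids()) | set(self.group2.gene_ids())
        if not retained_set <= known:
            raise ValueError("unknown gene id in s_retained")

    # -- (de)serialisation -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["conversions"] = [asdict(c) for c in self.conversions]
        data["pseudogenes"] = [asdict(p) for p in self.pseudogenes]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        for key in ("group1", "group2"):
            if key in data and isinstance(data[key], dict):
                data[key] = SubgroupConfig(**data[key])
        if "conversions" in data:
            data["conversions"] = [
                ConversionEvent(**{**c, "tract": tuple(c["tract"])})
                if isinstance(c, dict)
                else c
                for c in data["conversions"]
            ]
        if "pseudogenes" in data:
            data["pseudogenes"] = [
                PseudogeneEvent(**p) if isinstance(p, dict) else p
                for p in data["pseudogenes"]
            ]
        if "intron_lengths" in data:
            data["intron_lengths"] = tuple(data["intron_lengths"])
        if "selected_windows" in data:
            data["selected_windows"] = {
                k: tuple(v) for k, v in data["selected_windows"].items()
            }
        return cls(**data)

    @classmethod
    def default_scenario(cls) -> "SimConfig":
        return cls()


# --- truth tables -------------------------------------------------------------


@dataclass
class FamilyTruth:
    """Ground truth of one simulated family (the acceptance oracle)."""

    genes: dict[str, dict] = field(default_factory=dict)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    homeolog_pairs: list[tuple[str, str]] = field(default_factory=list)
    paralog_pairs: list[tuple[str, str]] = field(default_factory=list)
    paired_receptors: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    conversions: list[dict] = field(default_factory=list)
    pseudogenes: dict[str, list[str]] = field(default_factory=dict)
    lost_from_s: list[str] = field(default_factory=list)
    s_loss_fraction: float = 0.0
    omega_windows: dict[str, tuple[int, int]] = field(default_factory=dict)
    events: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "FamilyTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["ortholog_pairs"] = [tuple(p) for p in data["ortholog_pairs"]]
        data["homeolog_pairs"] = [tuple(p) for p in data["homeolog_pairs"]]
        data["paralog_pairs"] = [tuple(p) for p in data["paralog_pairs"]]
        data["paired_receptors"] = {
            k: [tuple(p) for p in v] for k, v in data["paired_receptors"].items()
        }
        data["omega_windows"] = {k: tuple(v) for k, v in data["omega_windows"].items()}
        return cls(**data)


# --- internal gene state ------------------------------------------------------

_EXON_KEYS = ("leader", "N", "IgC", "TM", "cyt")
_EXON_KIND = {"leader": "leader", "N": "N", "IgC": "IgC", "TM": "TM", "cyt": "cytoplasmic"}


@dataclass
class _GeneSeq:
    exons: dict[str, str]
    introns: list[str]

    def clone(self) -> "_GeneSeq":
        return _GeneSeq(dict(self.exons), list(self.introns))


@dataclass
class SimulatedLocus:
    species: str
    locus: str  # "" | "L" | "S"
    chromosome: str
    sequence: str
    genes: list[GeneModel]


@dataclass
class SimulationResult:
    config: SimConfig
    seed: int
    loci: list[SimulatedLocus]
    n_exons: dict[str, str]  # gene id -> N exon nt (coding orientation)
    cyt_peptides: dict[str, str]
    truth: FamilyTruth

    def write(self, outdir: str | Path) -> None:
        """Write chromosome FASTA, GFF3, exon FASTA, truth and manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        chroms = {loc.chromosome: loc.sequence for loc in self.loci}
        prio.write_fasta(chroms, outdir / "chromosomes.fa")
        records = []
        for loc in self.loci:
            records.extend(prio.genes_to_gff_records(loc.genes, source="pairedrec-sim"))
        prio.write_gff3(records, outdir / "genes.gff3")
        prio.write_fasta(self.n_exons, outdir / "n_exons.fa")
        self.truth.to_json(outdir / "truth.json")
        self.config.to_yaml(outdir / "config.yaml")
        manifest = {
            "seed": self.seed,
            "files": ["chromosomes.fa", "genes.gff3", "n_exons.fa", "truth.json", "config.yaml"],
            "loci": [
                {"species": l.species, "locus": l.locus, "chromosome": l.chromosome,
                 "n_genes": len(l.genes)}
                for l in self.loci
            ],
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)


# --- the simulation -----------------------------------------------------------


def _window_omega(cfg: SimConfig) -> np.ndarray:
    om = np.full(cfg.n_codons, cfg.omega_background)
    for s, e in cfg.selected_windows.values():
        om[s:e] = cfg.omega_selected
    return om


def _ancestral_gene(cfg: SimConfig, rng: np.random.Generator) -> _GeneSeq:
    exons = {
        "leader": "ATG" + random_coding_sequence(cfg.leader_codons - 1, rng),
        "N": random_coding_sequence(cfg.n_codons, rng),
        "IgC": random_coding_sequence(cfg.igc_codons, rng),
        "TM": random_coding_sequence(cfg.tm_codons, rng),
        # tyrosine-free ancestral tail: motif content is cassette-driven
        "cyt": random_coding_sequence(cfg.cyt_codons, rng, exclude_aas="Y"),
    }
    introns = []
    for ln in cfg.intron_lengths:
        inner = "".join(BASES[i] for i in rng.integers(0, 4, size=ln - 4))
        introns.append("GT" + inner + "AG")
    return _GeneSeq(exons, introns)


def _evolve_gene(
    gs: _GeneSeq,
    dt: float,
    cfg: SimConfig,
    n_exon_omega,
    rng: np.random.Generator,
) -> _GeneSeq:
    if dt <= 0:
        return gs.clone()
    branch = cfg.syn_rate * dt
    bg = cfg.omega_background
    out = _GeneSeq({}, [])
    out.exons["leader"] = evolve_codon_sequence(gs.exons["leader"], branch, bg, rng, cfg.kappa)
    out.exons["N"] = evolve_codon_sequence(gs.exons["N"], branch, n_exon_omega, rng, cfg.kappa)
    out.exons["IgC"] = evolve_codon_sequence(gs.exons["IgC"], branch, bg, rng, cfg.kappa)
    out.exons["TM"] = evolve_codon_sequence(gs.exons["TM"], branch, bg, rng, cfg.kappa)
    out.exons["cyt"] = evolve_codon_sequence(gs.exons["cyt"], branch, 0.0, rng, cfg.kappa)
    intron_rate = branch * cfg.intron_rate_multiplier
    for intron in gs.introns:
        frozen = {0, 1, len(intron) - 2, len(intron) - 1}
        out.introns.append(evolve_nucleotide_sequence(intron, intron_rate, rng, frozen))
    return out


def _subgroup_join_schedule(sub: SubgroupConfig, cfg: SimConfig):
    """Caterpillar duplication history with the paired cherry at the bottom.

    Returns (tree, root_time); tree nodes are ("leaf", gene_id) or
    ("join", time, left, right).
    """
    inh = sub.gene_id(sub.inhibitory)
    act = [sub.gene_id(i) for i in sub.activating]
    node = ("leaf", inh)
    t = cfg.cherry_time
    for a in act:
        node = ("join", t, node, ("leaf", a))
        t += cfg.dup_step
    for gid in sub.gene_ids():
        if gid == inh or gid in act:
            continue
        node = ("join", t, node, ("leaf", gid))
        t += cfg.dup_step
    return node, t - cfg.dup_step


def simulate_family(cfg: SimConfig | None = None, seed: int = 0) -> SimulationResult:
    """Simulate the full family history and assemble both species' loci.

    Deterministic under a fixed seed (byte-identical outputs).
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    truth = FamilyTruth(omega_windows=dict(cfg.selected_windows))
    window_om = _window_omega(cfg)
    bg = cfg.omega_background

    subgroups = {"group1": cfg.group1, "group2": cfg.group2}
    inhibitory_ids = {
        sub.gene_id(sub.inhibitory) for sub in subgroups.values()
    }
    activating_ids = set()
    for sub in subgroups.values():
        activating_ids |= {sub.gene_id(i) for i in sub.activating}
    dup_by_gene = {d["gene"]: d for d in cfg.recent_duplications}
    for d in cfg.recent_duplications:
        if d["gene"] in activating_ids:
            activating_ids.add(d["gene"] + d["suffix"])

    def n_omega(gene_id: str):
        return window_om if gene_id in inhibitory_ids else bg

    # present-day sequences per (gene id, species, locus)
    tips: dict[tuple[str, str, str], _GeneSeq] = {}
    subgroup_of: dict[str, str] = {}

    def run_species_phase(gene_id: str, gs: _GeneSeq):
        """Evolve one gene lineage from speciation time to the present."""
        om = n_omega(gene_id)
        # species A, with optional recent duplication
        dup = dup_by_gene.get(gene_id)
        if dup and dup["species"] == "A":
            at = _evolve_gene(gs, cfg.speciation_time - dup["time"], cfg, om, rng)
            tips[(gene_id, "A", "")] = _evolve_gene(at, dup["time"], cfg, om, rng)
            dup_id = gene_id + dup["suffix"]
            tips[(dup_id, "A", "")] = _evolve_gene(at, dup["time"], cfg, n_omega(dup_id), rng)
            subgroup_of[dup_id] = subgroup_of[gene_id]
            truth.events.append(
                {"type": "duplication", "time": dup["time"], "genes": [gene_id, dup_id]}
            )
        else:
            tips[(gene_id, "A", "")] = _evolve_gene(gs, cfg.speciation_time, cfg, om, rng)
        # species B: allotetraploid split into L and S
        pre = _evolve_gene(gs, cfg.speciation_time - cfg.allotetraploid_time, cfg, om, rng)
        tips[(gene_id, "B", "L")] = _evolve_gene(pre, cfg.allotetraploid_time, cfg, om, rng)
        tips[(gene_id, "B", "S")] = _evolve_gene(pre, cfg.allotetraploid_time, cfg, om, rng)

    def run_tree(node, gs: _GeneSeq, t_from: float, group: str):
        if node[0] == "leaf":
            gene_id = node[1]
            subgroup_of[gene_id] = group
            evolved = _evolve_gene(gs, t_from - cfg.speciation_time, cfg, n_omega(gene_id), rng)
            run_species_phase(gene_id, evolved)
            return
        _, t_node, left, right = node
        evolved = _evolve_gene(gs, t_from - t_node, cfg, bg, rng)
        run_tree(left, evolved, t_node, group)
        run_tree(right, evolved.clone(), t_node, group)

    root1 = _ancestral_gene(cfg, rng)
    root2_exons = {}
    for key in _EXON_KEYS:
        om = cfg.subgroup_split_omega if key != "cyt" else 0.0
        root2_exons[key] = evolve_codon_sequence(
            root1.exons[key], cfg.subgroup_split_branch, om, rng, cfg.kappa
        )
    root2 = _GeneSeq(root2_exons, [ev for ev in (
        evolve_nucleotide_sequence(i, cfg.subgroup_split_branch * cfg.intron_rate_multiplier,
                                   rng, {0, 1, len(i) - 2, len(i) - 1})
        for i in root1.introns
    )])
    roots = {"group1": root1, "group2": root2}

    for group in ("group1", "group2"):
        tree, root_time = _subgroup_join_schedule(subgroups[group], cfg)
        run_tree(tree, roots[group], root_time, group)
        truth.events.append({"type": "subgroup_root", "group": group, "time": root_time})

    # gene conversions: copy the donor's present-day tract, then let the
    # acceptor tract drift for twice the event age (the pairwise
    # divergence accumulated since conversion)
    for ev in sorted(cfg.conversions, key=lambda e: (-e.time, e.acceptor, e.locus)):
        donor_key = (ev.donor, ev.species, ev.locus)
        acc_key = (ev.acceptor, ev.species, ev.locus)
        donor_seq = tips[donor_key].exons["N"]
        acc = tips[acc_key]
        converted = apply_conversion(acc.exons["N"], donor_seq, ev.tract)
        s, e = ev.tract
        tract_seq = converted[3 * s : 3 * e]
        om = np.asarray(np.broadcast_to(n_omega(ev.acceptor), (cfg.n_codons,)))[s:e]
        drifted = evolve_codon_sequence(tract_seq, 2 * ev.time * cfg.syn_rate, om, rng, cfg.kappa)
        acc.exons["N"] = converted[: 3 * s] + drifted + converted[3 * e :]
        truth.conversions.append(
            {
                "donor": _gene_name(ev.donor, ev.species, ev.locus),
                "acceptor": _gene_name(ev.acceptor, ev.species, ev.locus),
                "tract": list(ev.tract),
                "time": ev.time,
            }
        )
        truth.events.append({"type": "conversion", **asdict(ev), "tract": list(ev.tract)})

    # insert signaling cassettes into cytoplasmic exons
    off = cfg.cassette_offset
    for (gene_id, species, locus), gs in tips.items():
        cassette = None
        base = _base_id(gene_id, dup_by_gene)
        if base in inhibitory_ids or gene_id in inhibitory_ids:
            cassette = encode_peptide(ITIM_CASSETTE)
        elif gene_id in activating_ids:
            cassette = encode_peptide(ITAM_CASSETTE)
        if cassette:
            cyt = gs.exons["cyt"]
            gs.exons["cyt"] = cyt[: 3 * off] + cassette + cyt[3 * off + len(cassette) :]

    # programmed pseudogenization
    for pe in cfg.pseudogenes:
        gs = tips[(pe.gene, pe.species, pe.locus)]
        name = _gene_name(pe.gene, pe.species, pe.locus)
        if pe.mechanism == "internal_stop":
            n = gs.exons["N"]
            mid = (cfg.n_codons // 2) * 3
            gs.exons["N"] = n[:mid] + "TAA" + n[mid + 3 :]
            truth.pseudogenes.setdefault(name, []).append("internal stop")
        elif pe.mechanism == "splice_donor":
            intron = gs.introns[1]  # intron following the N exon
            gs.introns[1] = "CC" + intron[2:]
            truth.pseudogenes.setdefault(name, []).append("bad splice donor")
        elif pe.mechanism == "splice_acceptor":
            intron = gs.introns[0]  # intron preceding the N exon
            gs.introns[0] = intron[:-2] + "CC"
            truth.pseudogenes.setdefault(name, []).append("bad splice acceptor")
        else:
            raise ValueError(f"unknown pseudogene mechanism {pe.mechanism!r}")
        truth.events.append({"type": "pseudogenization", **asdict(pe)})

    # --- assemble loci --------------------------------------------------------
    retained_s = set(cfg.s_retained)
    all_bases = cfg.group1.gene_ids() + cfg.group2.gene_ids()

    def locus_gene_order(species: str, locus: str) -> list[str]:
        order = []
        for base in all_bases:
            if locus == "S" and base not in retained_s:
                continue
            order.append(base)
            dup = dup_by_gene.get(base)
            if dup and dup["species"] == species and not locus:
                order.append(base + dup["suffix"])
        return order

    loci_spec = [("A", "", "chrA7"), ("B", "L", "chrB7L"), ("B", "S", "chrB7S")]
    loci: list[SimulatedLocus] = []
    n_exon_fasta: dict[str, str] = {}
    cyt_peptides: dict[str, str] = {}
    from Bio.Seq import Seq as _Seq

    for species, locus, chrom in loci_spec:
        cursor = 0
        seq_parts: list[str] = []
        genes: list[GeneModel] = []
        for base in locus_gene_order(species, locus):
            spacer_len = cfg.spacer_mean + int(
                rng.integers(-cfg.spacer_jitter, cfg.spacer_jitter + 1)
            )
            spacer = "".join(BASES[i] for i in rng.integers(0, 4, size=spacer_len))
            seq_parts.append(spacer)
            cursor += spacer_len
            key = (base, species, "" if species == "A" else locus)
            gs = tips[key]
            strand = "-" if base in activating_ids else "+"
            block_parts = []
            exon_offsets = []
            off_nt = 0
            for k, ek in enumerate(_EXON_KEYS):
                exon_seq = gs.exons[ek]
                exon_offsets.append((ek, off_nt, off_nt + len(exon_seq)))
                block_parts.append(exon_seq)
                off_nt += len(exon_seq)
                if k < len(gs.introns):
                    block_parts.append(gs.introns[k])
                    off_nt += len(gs.introns[k])
            block = "".join(block_parts)
            gstart = cursor
            gend = cursor + len(block)
            if strand == "-":
                seq_parts.append(str(_Seq(block).reverse_complement()))
            else:
                seq_parts.append(block)
            cursor = gend
            name = _gene_name(base, species, locus)
            exons = []
            for ek, s_off, e_off in exon_offsets:
                if strand == "+":
                    es, ee = gstart + s_off, gstart + e_off
                else:
                    es, ee = gend - e_off, gend - s_off
                exons.append(Exon(es, ee, _EXON_KIND[ek]))
            gene = GeneModel(
                id=name,
                chromosome=chrom,
                strand=strand,
                exons=exons,
                subgroup=subgroup_of[base],
                homeolog=locus if species == "B" else "",
                anchoring=cfg.anchoring_overrides.get(base, "TM"),
                species=species,
            )
            genes.append(gene)
            n_exon_fasta[name] = gs.exons["N"]
            cyt_peptides[name] = str(_Seq(gs.exons["cyt"]).translate())
            role = (
                "inhibitory"
                if base in inhibitory_ids
                else "activating"
                if base in activating_ids
                else "none"
            )
            truth.genes[name] = {
                "base": base,
                "species": species,
                "locus": locus,
                "chromosome": chrom,
                "strand": strand,
                "subgroup": subgroup_of[base],
                "role": role,
                "pseudogene": name in truth.pseudogenes,
                "selected_windows": base in inhibitory_ids,
            }
        tail = "".join(
            BASES[i] for i in rng.integers(0, 4, size=cfg.spacer_mean)
        )
        seq_parts.append(tail)
        loci.append(SimulatedLocus(species, locus, chrom, "".join(seq_parts), genes))

    # --- truth relations ------------------------------------------------------
    pseudo = set(truth.pseudogenes)
    # conversion overwrites the acceptor's N exon with donor sequence, so
    # the acceptor's cross-species orthology is no longer recoverable from
    # N-domain similarity; such pairs are excluded from the truth ortholog
    # set (they surface as within-species paralog groups instead)
    acceptors = {c["acceptor"] for c in truth.conversions}

    def intact(name: str) -> bool:
        return name not in pseudo

    def recoverable(x: str, y: str) -> bool:
        return intact(x) and intact(y) and x not in acceptors and y not in acceptors

    for base in all_bases:
        a_name = _gene_name(base, "A", "")
        l_name = _gene_name(base, "B", "L")
        s_name = _gene_name(base, "B", "S")
        if recoverable(a_name, l_name):
            truth.ortholog_pairs.append((a_name, l_name))
        if base in retained_s:
            if recoverable(a_name, s_name):
                truth.ortholog_pairs.append((a_name, s_name))
            if intact(l_name) and intact(s_name):
                truth.homeolog_pairs.append((l_name, s_name))
        else:
            truth.lost_from_s.append(base)
        dup = dup_by_gene.get(base)
        if dup and dup["species"] == "A":
            dup_name = _gene_name(base + dup["suffix"], "A", "")
            if recoverable(dup_name, l_name):
                truth.ortholog_pairs.append((dup_name, l_name))
            if base in retained_s and recoverable(dup_name, s_name):
                truth.ortholog_pairs.append((dup_name, s_name))
            truth.paralog_pairs.append(tuple(sorted((a_name, dup_name))))
    truth.s_loss_fraction = len(truth.lost_from_s) / len(all_bases)

    # paired receptors and converted paralog pairs per locus
    for species, locus, _chrom in loci_spec:
        key = f"{species}{('.' + locus) if locus else ''}"
        pairs = []
        for group, sub in subgroups.items():
            inh_base = sub.gene_id(sub.inhibitory)
            inh_name = _gene_name(inh_base, species, locus)
            if inh_name not in truth.genes:
                continue
            act_bases = [sub.gene_id(i) for i in sub.activating]
            act_all = []
            for ab in act_bases:
                act_all.append(ab)
                dup = dup_by_gene.get(ab)
                if dup and dup["species"] == species and not locus:
                    act_all.append(ab + dup["suffix"])
            for ab in act_all:
                act_name = _gene_name(ab, species, locus)
                if act_name in truth.genes:
                    pairs.append((inh_name, act_name))
        truth.paired_receptors[key] = pairs
        # a converted (inhibitory, activating) pair is a mutual-nearest
        # paralog pair only when the inhibitory gene has a single partner
        # (with several partners the recent duplicates are each other's
        # closest relatives instead)
        by_inh: dict[str, list[str]] = {}
        for inh_name, act_name in pairs:
            by_inh.setdefault(inh_name, []).append(act_name)
        for inh_name, act_names in by_inh.items():
            if len(act_names) != 1:
                continue
            act_name = act_names[0]
            converted = any(
                c["acceptor"] == act_name and c["donor"] == inh_name
                for c in truth.conversions
            )
            if converted:
                truth.paralog_pairs.append(tuple(sorted((inh_name, act_name))))
    truth.paralog_pairs = sorted(set(truth.paralog_pairs))
    truth.ortholog_pairs.sort()
    truth.homeolog_pairs.sort()

    return SimulationResult(
        config=cfg,
        seed=seed,
        loci=loci,
        n_exons=n_exon_fasta,
        cyt_peptides=cyt_peptides,
        truth=truth,
    )


def _base_id(gene_id: str, dup_by_gene: dict) -> str:
    for base, dup in dup_by_gene.items():
        if gene_id == base + dup["suffix"]:
            return base
    return gene_id


def _gene_name(base: str, species: str, locus: str) -> str:
    return f"{base}_{species}{('.' + locus) if locus else ''}"
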