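"""End-to-end pipeline: annotate -> subgroup -> orthologs -> dN/dS ->
conversion scan -> paired receptors -> homeologous-locus comparison.

The pipeline consumes a simulator output directory (or equivalent
chromosome FASTA + GFF3 produced elsewhere), re-derives everything from
sequence -- motif classes, pseudogene status, subgroups, orthology,
selection statistics, conversion tracts, receptor pairs and locus
fates -- and writes one TSV per stage plus a human-readable markdown
report.  Stage outputs are cached keyed by input checksums so an
unchanged rerun reuses them; every threshold actually applied is echoed
into the report.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from . import io as prio
from .annotation import GeneModel, call_pseudogene, classify_motifs, scan_motifs
from .codon import CodonAlignment, cumulative_profile, edit_alignment, pairwise_dnds
from .conversion import check_exon_restriction, codon_to_genomic, detect_conversion_tracts
from .paired import compare_homeologous_loci, identify_paired_receptors, rank_selection
from .phylo import assign_subgroups, call_orthologs, distance_matrix_from_sequences

__all__ = ["RunConfig", "RunReport", "PipelineDependencyError", "run_pipeline"]

STAGES = ("annotate", "subgroups", "orthologs", "conversion", "dnds", "pairs", "loci")
_DEPS = {
    "annotate": (),
    "subgroups": ("annotate",),
    "orthologs": ("annotate", "subgroups"),
    "conversion": ("annotate", "subgroups"),
    "dnds": ("orthologs", "conversion"),
    "pairs": ("annotate", "subgroups"),
    "loci": ("annotate", "orthologs", "pairs"),
}


class PipelineDependencyError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_dir: Path
    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    identity_threshold: float = 80.0
    min_tract_len: int = 15
    alpha: float = 0.05
    reps: int = 999
    divergence_threshold: float = 0.01
    min_split_edge: float = 0.1

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in self.stages:
            missing = [d for d in _DEPS[stage] if d not in self.stages]
            if missing:
                raise PipelineDependencyError(
                    f"stage '{stage}' requires disabled stage(s): {', '.join(missing)}"
                )
        if not (self.input_dir / "chromosomes.fa").exists():
            raise FileNotFoundError(f"no chromosomes.fa in {self.input_dir}")
        if not (self.input_dir / "genes.gff3").exists():
            raise FileNotFoundError(f"no genes.gff3 in {self.input_dir}")


@dataclass
class RunReport:
    """Per-stage summaries of one pipeline run."""

    seed: int
    stages_run: list[str] = field(default_factory=list)
    stages_cached: list[str] = field(default_factory=list)
    summaries: dict[str, dict] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_markdown(self) -> str:
        lines = ["# pairedrec pipeline report", ""]
        lines.append(f"seed: {self.seed}")
        lines.append("thresholds: " + ", ".join(f"{k}={v}" for k, v in self.thresholds.items()))
        lines.append("")
        for stage in self.stages_run + self.stages_cached:
            summary = self.summaries.get(stage, {})
            cached = " (cached)" if stage in self.stages_cached else ""
            lines.append(f"## {stage}{cached}")
            for k, v in summary.items():
                lines.append(f"- {k}: {v}")
            lines.append("")
        if self.warnings:
            lines.append("## warnings")
            lines.extend(f"- {w}" for w in self.warnings)
        return "\n".join(lines)


def _checksum(*parts: str) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode())
        h.update(b"\0")
    return h.hexdigest()


def _file_checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Cache:
    def __init__(self, out_dir: Path):
        self.dir = out_dir / "cache"
        self.dir.mkdir(parents=True, exist_ok=True)

    def load(self, stage: str, checksum: str):
        path = self.dir / f"{stage}.json"
        if not path.exists():
            return None
        data = json.loads(path.read_text())
        if data.get("checksum") != checksum:
            return None
        return data["state"]

    def store(self, stage: str, checksum: str, state) -> None:
        (self.dir / f"{stage}.json").write_text(
            json.dumps({"checksum": checksum, "state": state}, sort_keys=True)
        )


def _translate(nt: str) -> str:
    return str(Seq(nt[: len(nt) - len(nt) % 3]).translate()).rstrip("*")


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the pipeline stages in dependency order."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    cache = _Cache(cfg.out_dir)
    report = RunReport(seed=cfg.seed)
    report.thresholds = {
        "identity_threshold_pct": cfg.identity_threshold,
        "min_tract_len_codons": cfg.min_tract_len,
        "alpha": cfg.alpha,
        "permutation_reps": cfg.reps,
        "n_exon_divergence_threshold": cfg.divergence_threshold,
        "min_split_edge": cfg.min_split_edge,
    }

    chrom_seqs = prio.read_fasta(cfg.input_dir / "chromosomes.fa")
    genes = prio.genes_from_gff3(cfg.input_dir / "genes.gff3")
    input_sum = _checksum(
        _file_checksum(cfg.input_dir / "chromosomes.fa"),
        _file_checksum(cfg.input_dir / "genes.gff3"),
        json.dumps(
            {k: v for k, v in report.thresholds.items()}, sort_keys=True
        ),
        str(cfg.seed),
    )

    state: dict[str, dict] = {}

    def run_stage(stage, func):
        if stage not in cfg.stages:
            return
        checksum = _checksum(stage, input_sum)
        cached = cache.load(stage, checksum)
        if cached is not None:
            state[stage] = cached
            report.stages_cached.append(stage)
        else:
            state[stage] = func()
            cache.store(stage, checksum, state[stage])
            report.stages_run.append(stage)
        report.summaries[stage] = state[stage].get("summary", {})

    # ---- annotate ------------------------------------------------------------
    def stage_annotate():
        rows = []
        for g in genes:
            chrom = chrom_seqs[g.chromosome]
            n_exons = g.exons_of_kind("N")
            cyt_exons = g.exons_of_kind("cytoplasmic")
            n_nt = "".join(g.exon_coding_seq(e, chrom) for e in n_exons)
            cyt_pep = "".join(_translate(g.exon_coding_seq(e, chrom)) for e in cyt_exons)
            motifs = scan_motifs(cyt_pep)
            mclass = classify_motifs(motifs)
            ps = call_pseudogene(g, chrom)
            rows.append(
                {
                    "id": g.id,
                    "chrom": g.chromosome,
                    "strand": g.strand,
                    "species": g.species or g.chromosome,
                    "homeolog": g.homeolog,
                    "n_exons": len(n_exons),
                    "motif_class": mclass,
                    "motifs": ",".join(f"{m.kind}@{m.offset}" for m in motifs) or ".",
                    "status": ps.status,
                    "reasons": ";".join(ps.reasons) or ".",
                    "n_nt": n_nt,
                    "n_peptide": _translate(n_nt),
                    "anchoring": g.anchoring,
                }
            )
        df = pd.DataFrame(rows)
        df.drop(columns=["n_nt", "n_peptide"]).to_csv(
            cfg.out_dir / "gene_table.tsv", sep="\t", index=False
        )
        summary = {
            "genes": len(rows),
            "pseudogenes": int((df["status"] == "pseudogene").sum()),
            "inhibitory": int((df["motif_class"] == "inhibitory").sum()),
            "activating": int((df["motif_class"] == "activating").sum()),
            "ambiguous": int((df["motif_class"] == "ambiguous").sum()),
        }
        return {"rows": rows, "summary": summary}

    run_stage("annotate", stage_annotate)

    def gene_rows():
        return state["annotate"]["rows"]

    def intact_rows():
        return [r for r in gene_rows() if r["status"] == "intact"]

    # ---- subgroups -----------------------------------------------------------
    def stage_subgroups():
        assignment = {}
        summary = {}
        for species in sorted({r["species"] for r in gene_rows()}):
            peps = {
                r["id"]: r["n_peptide"]
                for r in intact_rows()
                if r["species"] == species and r["n_peptide"]
            }
            sub = assign_subgroups(peps, min_split_edge=cfg.min_split_edge)
            # deterministic labels: the cluster holding the smallest id is group1
            for gid in sub.group1:
                assignment[gid] = "group1"
            for gid in sub.group2:
                assignment[gid] = "group2"
            summary[f"{species}_split_found"] = sub.split_found
            summary[f"{species}_within_identity"] = [round(x, 1) for x in sub.within_identity]
            summary[f"{species}_between_identity"] = [
                round(x, 1) if not math.isnan(x) else "NA" for x in sub.between_identity
            ]
        return {"assignment": assignment, "summary": summary}

    run_stage("subgroups", stage_subgroups)

    # ---- orthologs -----------------------------------------------------------
    def stage_orthologs():
        peps = {r["id"]: r["n_peptide"] for r in intact_rows() if r["n_peptide"]}
        species = {r["id"]: r["species"] for r in intact_rows()}
        tags = {r["id"]: r["homeolog"] for r in intact_rows() if r["homeolog"]}
        calls = call_orthologs(peps, species, tags)
        rows = [
            {
                "gene_a": c.gene_a,
                "species_a": c.species_a,
                "gene_b": c.gene_b,
                "species_b": c.species_b,
                "relation": c.relation,
                "distance": round(c.distance, 4),
                "reciprocal": c.reciprocal,
                "tie": c.tie,
            }
            for c in calls
        ]
        pd.DataFrame(rows).to_csv(cfg.out_dir / "orthology.tsv", sep="\t", index=False)
        summary = {
            rel: sum(r["relation"] == rel for r in rows)
            for rel in ("ortholog", "paralog", "homeolog")
        }
        return {"rows": rows, "summary": summary}

    run_stage("orthologs", stage_orthologs)

    # ---- conversion scan on inhibitory x activating pairs --------------------
    def stage_conversion():
        assignment = state["subgroups"]["assignment"]
        rows = []
        by_id = {g.id: g for g in genes}
        candidates = []
        for ri in intact_rows():
            if ri["motif_class"] != "inhibitory":
                continue
            for ra in intact_rows():
                if ra["motif_class"] != "activating":
                    continue
                if ri["chrom"] != ra["chrom"]:
                    continue
                if assignment.get(ri["id"]) != assignment.get(ra["id"]):
                    continue
                candidates.append((ri, ra))
        for ri, ra in candidates:
            aln = _codon_align(ri["n_nt"], ra["n_nt"], ri["id"], ra["id"])
            if aln is None:
                continue
            scan = detect_conversion_tracts(
                aln, min_len=cfg.min_tract_len, reps=cfg.reps, seed=cfg.seed, alpha=cfg.alpha
            )
            gene_i = by_id[ri["id"]]
            n_exon = gene_i.exons_of_kind("N")[0]
            if scan.status != "ok":
                rows.append(
                    {
                        "pair": f"{ri['id']}|{ra['id']}",
                        "status": scan.status,
                        "start": "NA",
                        "end": "NA",
                        "len": "NA",
                        "syn_in": "NA",
                        "nuc_diffs_in": "NA",
                        "p": "NA",
                        "exon_restricted": "NA",
                    }
                )
                continue
            for tract in scan.tracts:
                genomic = codon_to_genomic(
                    (tract.start, tract.end), n_exon.start, n_exon.end, gene_i.strand
                )
                conc = check_exon_restriction(genomic, (n_exon.start, n_exon.end), slack=10, tract=tract)
                rows.append(
                    {
                        "pair": f"{ri['id']}|{ra['id']}",
                        "status": "tract",
                        "start": tract.start,
                        "end": tract.end,
                        "len": tract.length,
                        "syn_in": round(tract.syn_inside, 4),
                        "nuc_diffs_in": tract.nuc_diffs_inside,
                        "p": tract.pvalue,
                        "exon_restricted": conc.exon_restricted,
                    }
                )
            if not scan.tracts:
                rows.append(
                    {
                        "pair": f"{ri['id']}|{ra['id']}",
                        "status": "no_tract",
                        "start": "NA",
                        "end": "NA",
                        "len": "NA",
                        "syn_in": "NA",
                        "nuc_diffs_in": "NA",
                        "p": "NA",
                        "exon_restricted": "NA",
                    }
                )
        df = pd.DataFrame(rows)
        if len(df):
            # Benjamini-Hochberg across tract p-values in the batch report
            tract_mask = df["status"] == "tract"
            pvals = pd.to_numeric(df.loc[tract_mask, "p"], errors="coerce")
            m = int(tract_mask.sum())
            if m:
                order = pvals.sort_values().index
                bh = pd.Series(index=df.index, dtype=float)
                running = 1.0
                for rank_idx, idx in enumerate(reversed(list(order)), start=0):
                    k = m - rank_idx
                    running = min(running, pvals[idx] * m / k)
                    bh[idx] = running
                df["p_bh"] = bh
        df.to_csv(cfg.out_dir / "conversion_tracts.tsv", sep="\t", index=False)
        n_tracts = sum(r["status"] == "tract" for r in rows)
        summary = {
            "candidate_pairs": len(candidates),
            "tracts": n_tracts,
            "exon_restricted": sum(r.get("exon_restricted") is True for r in rows),
        }
        return {"rows": rows, "summary": summary}

    run_stage("conversion", stage_conversion)

    # ---- dN/dS on ortholog/homeolog N exons ----------------------------------
    def stage_dnds():
        nt = {r["id"]: r["n_nt"] for r in gene_rows()}
        mclass = {r["id"]: r["motif_class"] for r in gene_rows()}
        # activating genes whose N exon carries a significant conversion
        # tract acquired it from an inhibitory donor; their apparent
        # ortholog divergence reflects the donor lineage, so they are
        # excluded from the selection ranking (but still tabulated)
        converted = {
            r["pair"].split("|")[1]
            for r in state["conversion"]["rows"]
            if r["status"] == "tract"
        }
        results = {}
        pair_class = {}
        rows = []
        for r in state["orthologs"]["rows"]:
            if r["relation"] not in ("ortholog", "homeolog"):
                continue
            a, b = r["gene_a"], r["gene_b"]
            key = f"{a}|{b}"
            aln = _codon_align(nt[a], nt[b], a, b)
            if aln is None:
                continue
            res = pairwise_dnds(aln)
            in_ranking = not ({a, b} & converted)
            if in_ranking:
                results[key] = res
                pair_class[key] = (
                    mclass[a] if mclass[a] == mclass[b] else f"{mclass[a]}/{mclass[b]}"
                )
            row = res.to_dict()
            row["relation"] = r["relation"]
            row["motif_class"] = mclass[a] if mclass[a] == mclass[b] else f"{mclass[a]}/{mclass[b]}"
            row["in_ranking"] = in_ranking
            rows.append(row)
            prof = cumulative_profile(aln)
            prof.to_dataframe().to_csv(
                cfg.out_dir / f"profile_{a}__{b}.tsv", sep="\t", index=False
            )
        ranking = rank_selection(results, pair_class)
        pd.DataFrame(rows).to_csv(cfg.out_dir / "dnds.tsv", sep="\t", index=False)
        rank_rows = [
            {
                "rank": i + 1,
                "pair": k,
                "dNdS": round(ranking.ratios[k], 4) if not math.isnan(ranking.ratios[k]) else "NA",
                "motif_class": pair_class.get(k, "NA"),
            }
            for i, k in enumerate(ranking.order)
        ]
        pd.DataFrame(rank_rows).to_csv(cfg.out_dir / "selection_ranking.tsv", sep="\t", index=False)
        top = rank_rows[0] if rank_rows else None
        summary = {
            "pairs_compared": len(rows),
            "excluded_converted": sorted(converted),
            "undefined_ratios": len(ranking.undefined),
            "top_pair": top["pair"] if top else "NA",
            "top_dNdS": top["dNdS"] if top else "NA",
            "top_motif_class": top["motif_class"] if top else "NA",
            "inhibitory_top": ranking.inhibitory_top,
        }
        return {
            "rows": rows,
            "ranking": rank_rows,
            "inhibitory_top": ranking.inhibitory_top,
            "summary": summary,
        }

    run_stage("dnds", stage_dnds)

    # ---- paired receptors ----------------------------------------------------
    def stage_pairs():
        assignment = state["subgroups"]["assignment"]
        mclass = {r["id"]: r["motif_class"] for r in intact_rows()}
        peps = {r["id"]: r["n_peptide"] for r in intact_rows()}
        gene_models = []
        for g in genes:
            if g.id not in mclass:
                continue
            g2 = GeneModel(
                id=g.id,
                chromosome=g.chromosome,
                strand=g.strand,
                exons=g.exons,
                subgroup=assignment.get(g.id, ""),
                homeolog=g.homeolog,
                anchoring=g.anchoring,
                species=g.species,
            )
            gene_models.append(g2)
        pairs = identify_paired_receptors(
            gene_models, mclass, peps, identity_threshold=cfg.identity_threshold
        )
        rows = [
            {
                "inhibitory": p.inhibitory,
                "activating": p.activating,
                "identity_pct": round(p.identity_pct, 2),
                "subgroup": p.subgroup,
                "distance_nt": p.genomic_distance,
            }
            for p in pairs
        ]
        pd.DataFrame(rows).to_csv(cfg.out_dir / "paired_receptors.tsv", sep="\t", index=False)
        ambiguous = sorted(r["id"] for r in intact_rows() if r["motif_class"] == "ambiguous")
        return {
            "rows": rows,
            "ambiguous": ambiguous,
            "summary": {"pairs": len(rows), "ambiguous_genes": len(ambiguous)},
        }

    run_stage("pairs", stage_pairs)

    # ---- homeologous locus comparison ---------------------------------------
    def stage_loci():
        by_tag: dict[str, list[GeneModel]] = {"L": [], "S": []}
        for g in genes:
            if g.homeolog in by_tag:
                by_tag[g.homeolog].append(g)
        if not by_tag["L"] or not by_tag["S"]:
            return {"summary": {"note": "no homeologous loci in input"}}
        from .phylo import OrthologyCall

        calls = [
            OrthologyCall(
                r["gene_a"], r["species_a"], r["gene_b"], r["species_b"],
                r["relation"], r["distance"], reciprocal=r["reciprocal"], tie=r["tie"],
            )
            for r in state["orthologs"]["rows"]
        ]
        mclass = {r["id"]: r["motif_class"] for r in gene_rows()}
        assignment = state["subgroups"]["assignment"]
        for g in by_tag["L"] + by_tag["S"]:
            g.subgroup = assignment.get(g.id, g.subgroup)
        pair_rows = state["pairs"]["rows"]
        chroms_l = {g.chromosome for g in by_tag["L"]}
        chroms_s = {g.chromosome for g in by_tag["S"]}
        pairs_l = [p for p in pair_rows if _pair_on(p, by_tag["L"])]
        pairs_s = [p for p in pair_rows if _pair_on(p, by_tag["S"])]
        comp = compare_homeologous_loci(
            by_tag["L"], by_tag["S"], calls, mclass, pairs_l, pairs_s
        )
        fate_rows = [
            {"gene": gid, "fate": fate} for gid, fate in comp.fates.items()
        ] + [{"gene": gid, "fate": "gained-in-b"} for gid in comp.gained_in_b]
        pd.DataFrame(fate_rows).to_csv(cfg.out_dir / "locus_comparison.tsv", sep="\t", index=False)
        summary = {
            "locus_a_genes": len(by_tag["L"]),
            "locus_b_genes": len(by_tag["S"]),
            "loss_fraction": round(comp.loss_fraction, 4),
            "by_subgroup": comp.by_subgroup,
            "by_motif_class": comp.by_motif_class,
            "paired_pair_survives_L": comp.paired_pair_survives_a,
            "paired_pair_survives_S": comp.paired_pair_survives_b,
        }
        return {
            "fates": comp.fates,
            "gained": comp.gained_in_b,
            "loss_fraction": comp.loss_fraction,
            "summary": summary,
        }

    run_stage("loci", stage_loci)

    (cfg.out_dir / "report.md").write_text(report.to_markdown())
    return report


def _pair_on(pair_row: dict, locus_genes: list[GeneModel]) -> bool:
    ids = {g.id for g in locus_genes}
    return pair_row["inhibitory"] in ids and pair_row["activating"] in ids


def _codon_align(nt_a: str, nt_b: str, id_a: str, id_b: str) -> CodonAlignment | None:
    """Codon alignment of two N-exon nucleotide sequences.

    Equal-length sequences are paired column-wise; unequal lengths go
    through a global nucleotide alignment before gap editing.
    """
    try:
        if len(nt_a) == len(nt_b):
            return edit_alignment(nt_a, nt_b, id_a, id_b)
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -1
        aln = aligner.align(nt_a, nt_b)[0]
        return edit_alignment(str(aln[0]), str(aln[1]), id_a, id_b)
    except ValueError:
        return None
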