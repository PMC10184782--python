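"""Derived substitutions and codon-level consequence annotation.

Homozygous (fixed) substitutions are called as positions where the focal
reference and a coordinate-matched reconstructed ancestral sequence
carry distinct unambiguous bases. Single-nucleotide changes are then
classified against gene models with the standard genetic code:
synonymous (same amino acid), missense (different non-stop amino acid),
or loss of function (stop-gained, stop-lost, start-lost). Only point
substitutions are modeled, so splice and frameshift classes are out of
scope by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .errors import InvalidParameterError, MalformedInputError

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# standard genetic code; '*' denotes stop
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SEVERITY = {"LOF": 3, "missense": 2, "synonymous": 1, "noncoding": 0}


@dataclass(frozen=True)
class SubstitutionSet:
    """Derived single-nucleotide changes relative to the ancestral sequence."""

    records: pd.DataFrame  # contig, pos (0-based), ancestral, derived, zygosity
    n_skipped_ambiguous: int

    def __len__(self) -> int:
        return len(self.records)


def call_derived_substitutions(focal_fasta: str, ancestral_fasta: str) -> SubstitutionSet:
    """Positions where focal and ancestral sequences differ.

    Both FASTAs must share contig names and lengths (coordinate-matched).
    Sites where either sequence carries N or any ambiguity code are
    skipped and counted in ``n_skipped_ambiguous``. The focal base is
    recorded as derived, the ancestral base as ancestral; zygosity is
    "fixed" (homozygous substitution).
    """
    focal = Fasta(focal_fasta)
    anc = Fasta(ancestral_fasta)
    fk, ak = list(focal.keys()), list(anc.keys())
    if set(fk) != set(ak):
        first = sorted(set(fk) ^ set(ak))[0]
        raise MalformedInputError(f"contig sets differ; first mismatch: {first}")
    rows = []
    n_skip = 0
    valid = np.frombuffer(b"ACGT", dtype=np.uint8)
    for contig in fk:
        f = np.frombuffer(str(focal[contig][:]).upper().encode(), dtype=np.uint8)
        a = np.frombuffer(str(anc[contig][:]).upper().encode(), dtype=np.uint8)
        if len(f) != len(a):
            raise MalformedInputError(
                f"contig {contig} length mismatch: focal {len(f)} vs ancestral {len(a)}"
            )
        ok = np.isin(f, valid) & np.isin(a, valid)
        n_skip += int((~ok).sum())
        diff = np.nonzero(ok & (f != a))[0]
        for pos in diff:
            rows.append((contig, int(pos), chr(a[pos]), chr(f[pos]), "fixed"))
    records = pd.DataFrame(rows, columns=["contig", "pos", "ancestral", "derived", "zygosity"])
    return SubstitutionSet(records=records, n_skipped_ambiguous=n_skip)


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene as ordered CDS intervals (0-based half-open).

    ``cds`` intervals are stored in genomic order; ``strand`` determines
    transcription direction (minus-strand CDS sequence is the reverse
    complement read from the last interval backwards). Total CDS length
    must be a multiple of 3.
    """

    gene_id: str
    contig: str
    strand: str
    cds: tuple[tuple[int, int], ...]
    impc_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvalidParameterError(f"strand must be + or -, got {self.strand}")
        total = sum(e - s for s, e in self.cds)
        if total % 3 != 0:
            raise InvalidParameterError(
                f"gene {self.gene_id}: CDS length {total} not a multiple of 3"
            )
        prev = None
        for s, e in self.cds:
            if prev is not None and s < prev:
                raise InvalidParameterError(f"gene {self.gene_id}: CDS intervals overlap/disordered")
            prev = e

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def genome_to_cds(self, pos: int) -> int | None:
        """Map a genomic position to its 0-based CDS coordinate, or None."""
        off = 0
        for s, e in self.cds:
            if s <= pos < e:
                fwd = off + (pos - s)
                return fwd if self.strand == "+" else self.cds_length - 1 - fwd
            off += e - s
        return None

    def cds_sequence(self, seq: str) -> str:
        """CDS nucleotide sequence in transcription direction.

        ``seq`` is the full contig sequence.
        """
        parts = [seq[s:e].upper() for s, e in self.cds]
        joined = "".join(parts)
        if self.strand == "-":
            joined = "".join(COMPLEMENT.get(b, "N") for b in reversed(joined))
        return joined


def load_gene_models(gff3_path: str, impc_tsv: str | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 (+ optional IMPC viability table).

    Genes whose total CDS length is not a multiple of 3 are skipped with a
    warning. The IMPC table has columns gene_id, class with class in
    {lethal, subviable, viable}; genes absent from it get class "unknown".
    """
    impc: dict[str, str] = {}
    if impc_tsv is not None:
        t = pd.read_csv(impc_tsv, sep="\t")
        bad = set(t["class"]) - {"lethal", "subviable", "viable"}
        if bad:
            raise MalformedInputError(f"unknown IMPC classes: {sorted(bad)}")
        impc = dict(zip(t["gene_id"], t["class"]))
    db = gffutils.create_db(
        gff3_path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        cds = sorted(
            (f.start - 1, f.end)  # GFF3 is 1-based closed
            for f in db.children(gene, featuretype="CDS")
        )
        if not cds:
            continue
        total = sum(e - s for s, e in cds)
        if total % 3 != 0:
            logger.warning("gene %s: CDS length %d not multiple of 3; skipped", gene.id, total)
            continue
        genes.append(GeneModel(
            gene_id=gene.id, contig=gene.seqid, strand=gene.strand,
            cds=tuple(cds), impc_class=impc.get(gene.id, "unknown"),
        ))
    return genes


# ---------------------------------------------------------------------------
# consequence annotation


@dataclass(frozen=True)
class ConsequenceCall:
    contig: str
    pos: int  # 0-based
    base_from: str
    base_to: str
    gene_id: str | None
    category: str  # synonymous | missense | LOF | noncoding
    lof_type: str | None  # stop-gained | stop-lost | start-lost
    codon_before: str | None
    codon_after: str | None


def _classify_codon_change(codon_before: str, codon_after: str, codon_index: int,
                           n_codons: int) -> tuple[str, str | None]:
    aa_before = CODON_TABLE[codon_before]
    aa_after = CODON_TABLE[codon_after]
    if codon_index == 0 and aa_before == "M" and aa_after != "M":
        return "LOF", "start-lost"
    if aa_before != "*" and aa_after == "*":
        return "LOF", "stop-gained"
    if aa_before == "*" and aa_after != "*":
        return "LOF", "stop-lost"
    if aa_before == aa_after:
        return "synonymous", None
    return "missense", None


def annotate_consequence(
    contig: str,
    pos: int,
    base_from: str,
    base_to: str,
    genes: list[GeneModel],
    contig_seqs: dict[str, str],
) -> ConsequenceCall:
    """Classify the coding consequence of a single-base change.

    ``pos`` is 0-based on the reference contig; ``base_from``/``base_to``
    are the plus-strand alleles being compared (ancestral vs derived for
    substitutions, REF vs ALT for heterozygous variants). The codon
    context comes from the reference sequence with the site replaced by
    each allele in turn; minus-strand genes are handled by reverse
    complement. Variants hitting multiple genes keep the most severe
    consequence (LOF > missense > synonymous), ties by lexicographic
    gene_id.
    """
    if contig not in contig_seqs:
        raise InvalidParameterError(f"variant contig {contig} absent from reference")
    if base_from == base_to:
        raise InvalidParameterError("base_from and base_to must differ")
    for b in (base_from, base_to):
        if b not in BASES:
            raise InvalidParameterError(f"invalid base {b!r}")
    seq = contig_seqs[contig]
    best: ConsequenceCall | None = None
    for gene in sorted(genes, key=lambda g: g.gene_id):
        if gene.contig != contig:
            continue
        cds_pos = gene.genome_to_cds(pos)
        if cds_pos is None:
            continue
        cds_seq = gene.cds_sequence(seq)
        if gene.strand == "+":
            b_from, b_to = base_from, base_to
        else:
            b_from, b_to = COMPLEMENT[base_from], COMPLEMENT[base_to]
        ci, within = divmod(cds_pos, 3)
        codon_ref = cds_seq[3 * ci: 3 * ci + 3]
        codon_before = codon_ref[:within] + b_from + codon_ref[within + 1:]
        codon_after = codon_ref[:within] + b_to + codon_ref[within + 1:]
        if "N" in codon_before or "N" in codon_after:
            continue
        category, lof_type = _classify_codon_change(
            codon_before, codon_after, ci, len(cds_seq) // 3
        )
        call = ConsequenceCall(
            contig=contig, pos=pos, base_from=base_from, base_to=base_to,
            gene_id=gene.gene_id, category=category, lof_type=lof_type,
            codon_before=codon_before, codon_after=codon_after,
        )
        if best is None or SEVERITY[category] > SEVERITY[best.category]:
            best = call
    if best is None:
        return ConsequenceCall(
            contig=contig, pos=pos, base_from=base_from, base_to=base_to,
            gene_id=None, category="noncoding", lof_type=None,
            codon_before=None, codon_after=None,
        )
    return best


def annotate_variants(
    variants: pd.DataFrame,
    genes: list[GeneModel],
    ref_fasta: str,
) -> pd.DataFrame:
    """Annotate a table of variants (contig, pos, base_from, base_to, zygosity).

    Returns one row per variant with category, gene_id, lof_type,
    codon_before/after and the gene's IMPC class.
    """
    fa = Fasta(ref_fasta)
    seqs = {k: str(fa[k][:]).upper() for k in fa.keys()}
    impc = {g.gene_id: g.impc_class for g in genes}
    rows = []
    for rec in variants.itertuples(index=False):
        call = annotate_consequence(
            rec.contig, int(rec.pos), rec.base_from, rec.base_to, genes, seqs
        )
        rows.append({
            "contig": call.contig, "pos": call.pos,
            "base_from": call.base_from, "base_to": call.base_to,
            "zygosity": rec.zygosity, "gene_id": call.gene_id,
            "category": call.category, "lof_type": call.lof_type,
            "codon_before": call.codon_before, "codon_after": call.codon_after,
            "impc_class": impc.get(call.gene_id, "unknown") if call.gene_id else None,
        })
    return pd.DataFrame(rows)


def read_het_variants(vcf_path: str) -> pd.DataFrame:
    """Heterozygous biallelic SNVs from a VCF as (contig, pos, base_from, base_to)."""
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    rows = []
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            continue
        if v.gt_types[0] != vcf.HET:
            continue
        rows.append((v.CHROM, v.POS - 1, v.REF.upper(), v.ALT[0].upper(), "heterozygous"))
    return pd.DataFrame(rows, columns=["contig", "pos", "base_from", "base_to", "zygosity"])


def polarize_heterozygous(
    hets: pd.DataFrame, ancestral_fasta: str
) -> pd.DataFrame:
    """Mark the derived allele of heterozygous variants against the ancestor.

    The ALT allele is derived when REF matches the ancestral base;
    otherwise the site is flagged unpolarized (excluded from derived
    tallies).
    """
    anc = Fasta(ancestral_fasta)
    seqs = {k: str(anc[k][:]).upper() for k in anc.keys()}
    polarized = []
    for rec in hets.itertuples(index=False):
        a = seqs[rec.contig][rec.pos]
        polarized.append(a == rec.base_from)
    out = hets.copy()
    out["polarized"] = polarized
    return out
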