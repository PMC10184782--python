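"""Genome-wide deleterious-load summary statistics.

Derived substitutions at evolutionarily conserved sites (phyloP > 2.27)
and nonsynonymous changes in protein-coding genes are treated as
predominantly deleterious. Fixed substitutions proxy drift load;
heterozygous variants proxy segregating load. Proportions of missense
and loss-of-function changes are expressed relative to all coding point
mutations (synonymous + missense + LOF), overall and within
knockout-mouse viability classes (IMPC lethal/subviable/viable) used as
a proxy for gene essentiality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptySupportError, InvalidParameterError, UndefinedMomentError

PHYLOP_THRESHOLD = 2.27
IMPC_CLASSES = ("lethal", "subviable", "viable", "unknown")


def read_score_bed(path: str) -> pd.DataFrame:
    """Read a 4-column BED score track (contig, start, end, score)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["contig", "start", "end", "score"],
        dtype={"contig": str, "start": np.int64, "end": np.int64, "score": float},
    )
    return df.sort_values(["contig", "start"], kind="mergesort").reset_index(drop=True)


def score_positions(positions: pd.DataFrame, score_bed: pd.DataFrame) -> np.ndarray:
    """Score per (contig, pos) site from a sorted interval track; NaN if unscored."""
    out = np.full(len(positions), np.nan)
    for contig, grp in score_bed.groupby("contig"):
        grp = grp.sort_values("start", kind="mergesort")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        scores = grp["score"].to_numpy()
        sel = positions["contig"] == contig
        pos = positions.loc[sel, "pos"].to_numpy()
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = (k >= 0) & (pos < ends[np.clip(k, 0, None)])
        vals = np.full(len(pos), np.nan)
        vals[ok] = scores[k[ok]]
        out[np.flatnonzero(sel.to_numpy())] = vals
    return out


def classify_conserved(
    subs: pd.DataFrame,
    score_bed: pd.DataFrame | str,
    threshold: float = PHYLOP_THRESHOLD,
) -> tuple[int, int, float]:
    """Proportion of scored substitutions at conserved sites.

    Substitutions are intersected with the score track; the proportion is
    n(score > threshold) / n(scored) with a STRICT inequality at the
    threshold. Unscored substitutions are excluded from both counts.
    Returns (n_scored, n_conserved, proportion).
    """
    if not np.isfinite(threshold):
        raise InvalidParameterError(f"threshold must be finite, got {threshold}")
    bed = read_score_bed(score_bed) if isinstance(score_bed, str) else score_bed
    scores = score_positions(subs, bed)
    scored = scores[np.isfinite(scores)]
    if scored.size == 0:
        raise EmptySupportError("no substitution overlaps the score track")
    n_cons = int((scored > threshold).sum())
    return int(scored.size), n_cons, n_cons / scored.size


def phylop_kurtosis(scores, excess: bool = False) -> float:
    """Pearson kurtosis m4/m2^2 of conservation scores at substitution sites.

    Population moments; Normal data give 3 (``excess=True`` subtracts 3).
    Describes the weight of the extreme-conservation tail.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise UndefinedMomentError(f"need >= 4 scores, got {x.size}")
    if np.var(x) == 0:
        raise UndefinedMomentError("scores have zero variance; kurtosis undefined")
    k = float(stats.kurtosis(x, fisher=False, bias=True))
    return k - 3.0 if excess else k


@dataclass(frozen=True)
class LoadSummary:
    """Proportions of deleterious coding mutations, overall and by IMPC class.

    ``table`` has one row per (zygosity, impc_class) cell — zygosity in
    {fixed, heterozygous}, impc_class in {all, lethal, subviable, viable,
    unknown} — with counts n_synonymous, n_missense, n_lof, n_coding and
    proportions prop_missense, prop_lof (NaN where n_coding == 0,
    reported as undefined rather than 0).
    """

    table: pd.DataFrame
    prop_conserved_subs: float | None = None
    phylop_kurtosis: float | None = None

    def cell(self, zygosity: str, impc_class: str = "all") -> pd.Series:
        m = (self.table["zygosity"] == zygosity) & (self.table["impc_class"] == impc_class)
        if not m.any():
            raise KeyError((zygosity, impc_class))
        return self.table[m].iloc[0]


def load_proportions(calls: pd.DataFrame, impc_classes: dict[str, str] | None = None) -> LoadSummary:
    """Missense/LOF proportions of coding point mutations by zygosity and class.

    ``calls`` is the annotated variant table (columns zygosity, category,
    gene_id, and optionally impc_class). The denominator in every cell is
    the count of coding point mutations (synonymous + missense + LOF) in
    that cell; noncoding calls never enter. Cells with zero coding
    mutations yield NaN proportions.
    """
    df = calls.copy()
    if "impc_class" not in df.columns or df["impc_class"].isna().all():
        if impc_classes is None:
            df["impc_class"] = "unknown"
        else:
            df["impc_class"] = df["gene_id"].map(impc_classes).fillna("unknown")
    coding = df[df["category"].isin(["synonymous", "missense", "LOF"])]
    rows = []
    for zyg in ("fixed", "heterozygous"):
        zsub = coding[coding["zygosity"] == zyg]
        for cls in ("all",) + IMPC_CLASSES:
            cell = zsub if cls == "all" else zsub[zsub["impc_class"] == cls]
            n_syn = int((cell["category"] == "synonymous").sum())
            n_mis = int((cell["category"] == "missense").sum())
            n_lof = int((cell["category"] == "LOF").sum())
            n_cod = n_syn + n_mis + n_lof
            rows.append({
                "zygosity": zyg, "impc_class": cls,
                "n_synonymous": n_syn, "n_missense": n_mis, "n_lof": n_lof,
                "n_coding": n_cod,
                "prop_missense": n_mis / n_cod if n_cod else np.nan,
                "prop_lof": n_lof / n_cod if n_cod else np.nan,
            })
    return LoadSummary(table=pd.DataFrame(rows))


def summarize_load(
    calls: pd.DataFrame,
    subs: pd.DataFrame,
    score_bed: pd.DataFrame | str,
    impc_classes: dict[str, str] | None = None,
    threshold: float = PHYLOP_THRESHOLD,
) -> LoadSummary:
    """Full load summary: proportions table + conserved fraction + kurtosis."""
    base = load_proportions(calls, impc_classes)
    bed = read_score_bed(score_bed) if isinstance(score_bed, str) else score_bed
    _, _, prop_cons = classify_conserved(subs, bed, threshold)
    scores = score_positions(subs, bed)
    kurt = phylop_kurtosis(scores[np.isfinite(scores)])
    return LoadSummary(table=base.table, prop_conserved_subs=prop_cons, phylop_kurtosis=kurt)


def summary_row(summary: LoadSummary) -> dict[str, float]:
    """Flatten a LoadSummary into the genome-wide feature columns."""
    def p(zyg, cls):
        try:
            return float(summary.cell(zyg, cls)["prop_missense"])
        except KeyError:
            return np.nan

    out = {
        "prop_conserved_subs": summary.prop_conserved_subs,
        "phylop_kurtosis": summary.phylop_kurtosis,
        "prop_missense_fixed": p("fixed", "all"),
        "prop_missense_het": p("heterozygous", "all"),
        "prop_lof_het": float(summary.cell("heterozygous", "all")["prop_lof"]),
        "prop_missense_fixed_lethal": p("fixed", "lethal"),
        "prop_missense_fixed_viable": p("fixed", "viable"),
        "prop_missense_het_lethal": p("heterozygous", "lethal"),
        "prop_missense_het_viable": p("heterozygous", "viable"),
    }
    return out
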