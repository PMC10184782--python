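"""Runs of homozygosity from windowed heterozygosity.

The per-window ratio of heterozygous to callable positions in
non-overlapping 50-kb windows is bimodal in inbred genomes: a low mode
from runs of homozygosity (RoH) and a background mode from outbred
sequence. A two-component Gaussian mixture fitted by EM separates the
modes; windows with posterior weight > 0.5 on the lower-mean component
are called RoH, giving fRoH (fraction of the assessed genome in RoH),
genome-wide heterozygosity, and outbred heterozygosity (non-RoH windows
only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import InsufficientDataError, InvalidParameterError, MalformedInputError

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 50_000
MIN_CALLABLE_FRACTION = 0.5  # windows below this callable fraction are unassessed
MIN_ASSESSED_WINDOWS = 20


def read_mask_bed(path: str) -> dict[str, np.ndarray]:
    """Read a callable-site BED into per-contig (n, 2) interval arrays."""
    per: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MalformedInputError(f"{path}:{i}: BED line has < 3 fields")
            per.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    out = {}
    for contig, ivs in per.items():
        arr = np.array(sorted(ivs), dtype=np.int64)
        if np.any(arr[1:, 0] < arr[:-1, 1]):
            raise MalformedInputError(f"mask intervals overlap on contig {contig}")
        out[contig] = arr
    return out


def _overlap_in_window(ivs: np.ndarray, start: int, end: int) -> int:
    lo = np.clip(ivs[:, 0], start, end)
    hi = np.clip(ivs[:, 1], start, end)
    return int(np.maximum(hi - lo, 0).sum())


def compute_window_het(
    vcf_path: str,
    mask_bed: str,
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_callable_fraction: float = MIN_CALLABLE_FRACTION,
) -> pd.DataFrame:
    """Per-window heterozygous and callable counts from a VCF + callable BED.

    Windows tile each contig of the VCF header from 0 in non-overlapping
    steps of ``window_size`` (0-based half-open). Only biallelic SNVs with
    a heterozygous genotype that fall inside the callable mask are
    counted. Windows whose callable fraction is below
    ``min_callable_fraction`` are marked unassessed. Contigs present in
    the VCF but absent from the mask are skipped with a warning.

    Returns a DataFrame with columns contig, start, end, n_het,
    n_callable, ratio (NaN when n_callable is 0), assessed (bool).
    """
    if window_size < 1:
        raise InvalidParameterError(f"window_size must be >= 1, got {window_size}")
    mask = read_mask_bed(mask_bed)
    vcf = VCF(vcf_path)
    lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    het_counts: dict[str, np.ndarray] = {}
    for contig, length in lengths.items():
        het_counts[contig] = np.zeros(int(np.ceil(length / window_size)), dtype=np.int64)

    last = {}
    for v in vcf:
        contig = v.CHROM
        if contig not in lengths:
            raise MalformedInputError(f"VCF record on undeclared contig {contig}")
        pos0 = v.POS - 1
        if last.get(contig, -1) > pos0:
            raise MalformedInputError(f"VCF not coordinate-sorted at {contig}:{v.POS}")
        last[contig] = pos0
        if contig not in mask:
            continue
        if not v.is_snp or len(v.ALT) != 1:
            continue
        if v.gt_types[0] != vcf.HET:
            continue
        ivs = mask[contig]
        k = np.searchsorted(ivs[:, 0], pos0, side="right") - 1
        if k < 0 or pos0 >= ivs[k, 1]:
            continue  # het outside callable mask: not counted
        het_counts[contig][pos0 // window_size] += 1

    missing = set(lengths) - set(mask)
    for contig in sorted(missing):
        logger.warning("contig %s absent from mask; skipped", contig)

    rows = []
    for contig, length in lengths.items():
        if contig not in mask:
            continue
        ivs = mask[contig]
        for w, wstart in enumerate(range(0, length, window_size)):
            wend = min(wstart + window_size, length)
            n_callable = _overlap_in_window(ivs, wstart, wend)
            n_het = int(het_counts[contig][w])
            ratio = n_het / n_callable if n_callable > 0 else np.nan
            assessed = n_callable >= min_callable_fraction * (wend - wstart)
            rows.append((contig, wstart, wend, n_het, n_callable, ratio, assessed))
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "n_het", "n_callable", "ratio", "assessed"]
    )


# ---------------------------------------------------------------------------
# two-component Gaussian mixture by EM


@dataclass(frozen=True)
class GmmFit:
    weights: np.ndarray    # 2, sum to 1
    means: np.ndarray      # 2, ascending
    variances: np.ndarray  # 2, > 0
    loglik: float
    n_iter: int
    converged: bool
    degenerate: bool
    loglik_trace: np.ndarray


def fit_gmm_2(
    ratios,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> GmmFit:
    """EM fit of a two-component 1-D Gaussian mixture to window ratios.

    Initialization splits the data at the 10th percentile (lower component
    from the low tail where the RoH mode sits). Convergence when the
    log-likelihood improves by less than ``tol``. The ``degenerate`` flag
    is set when the fitted means are closer than one pooled standard
    deviation — effectively unimodal data where RoH calls would be
    arbitrary. ``seed`` is accepted for interface stability; the
    percentile initialization is deterministic.
    """
    x = np.asarray(ratios, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < MIN_ASSESSED_WINDOWS:
        raise InsufficientDataError(f"need >= {MIN_ASSESSED_WINDOWS} assessed windows, got {n}")

    q10 = np.quantile(x, 0.10)
    lo = x[x <= q10]
    hi = x[x > q10]
    if lo.size == 0 or hi.size == 0:  # massed data; start from a symmetric split
        lo, hi = x[: n // 2], x[n // 2:]
    var_floor = max(np.var(x) * 1e-8, 1e-20)
    means = np.array([lo.mean(), hi.mean()])
    variances = np.maximum(np.array([lo.var(), hi.var()]), var_floor)
    weights = np.array([lo.size / n, hi.size / n])

    def comp_logpdf(m, v):
        return -0.5 * (np.log(2 * np.pi * v) + (x - m) ** 2 / v)

    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = np.stack([
            np.log(weights[0]) + comp_logpdf(means[0], variances[0]),
            np.log(weights[1]) + comp_logpdf(means[1], variances[1]),
        ])
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(logp - lse)  # 2 x n
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp @ x) / nk
        variances = np.maximum((resp @ (x[None, :] - means[:, None]).T ** 2).diagonal() / nk, var_floor)
        # keep components ordered by mean
        if means[0] > means[1]:
            means, variances, weights = means[::-1].copy(), variances[::-1].copy(), weights[::-1].copy()
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll

    pooled_sd = np.sqrt(weights @ variances)
    degenerate = (means[1] - means[0]) < pooled_sd
    return GmmFit(
        weights=weights, means=means, variances=variances, loglik=trace[-1],
        n_iter=it, converged=converged, degenerate=degenerate,
        loglik_trace=np.asarray(trace),
    )


# ---------------------------------------------------------------------------
# RoH assignment


@dataclass(frozen=True)
class RoHCallset:
    assignments: pd.Series  # per-window: "RoH" | "non-RoH" | "unassessed"
    froh: float
    het_genomewide: float
    het_outbred: float
    fit: GmmFit


def assign_roh(table: pd.DataFrame, fit: GmmFit) -> RoHCallset:
    """Assign windows to RoH/non-RoH from mixture posteriors and summarize.

    A window is RoH iff the posterior responsibility of the lower-mean
    component strictly exceeds 0.5 (ties break to non-RoH). fRoH counts
    RoH among assessed windows only; het_genomewide pools het/callable
    over assessed windows; het_outbred over assessed non-RoH windows. A
    degenerate fit yields all non-RoH, fRoH = 0, and a logged warning.
    """
    assessed = table["assessed"].to_numpy()
    ratios = table["ratio"].to_numpy(dtype=float)
    labels = np.full(len(table), "unassessed", dtype=object)
    if fit.degenerate:
        logger.warning("degenerate mixture fit: no RoH called (fRoH = 0)")
        labels[assessed] = "non-RoH"
    else:
        logp = np.stack([
            np.log(fit.weights[k])
            - 0.5 * (np.log(2 * np.pi * fit.variances[k]) + (ratios - fit.means[k]) ** 2 / fit.variances[k])
            for k in (0, 1)
        ])
        with np.errstate(over="ignore"):
            post_low = 1.0 / (1.0 + np.exp(logp[1] - logp[0]))
        labels[assessed & (post_low > 0.5)] = "RoH"
        labels[assessed & (post_low <= 0.5)] = "non-RoH"

    is_roh = labels == "RoH"
    n_assessed = int(assessed.sum())
    froh = float(is_roh.sum() / n_assessed) if n_assessed else np.nan
    nhet = table["n_het"].to_numpy(dtype=float)
    ncall = table["n_callable"].to_numpy(dtype=float)
    het_gw = float(nhet[assessed].sum() / ncall[assessed].sum()) if ncall[assessed].sum() else np.nan
    out_mask = assessed & ~is_roh
    het_out = float(nhet[out_mask].sum() / ncall[out_mask].sum()) if ncall[out_mask].sum() else np.nan
    return RoHCallset(
        assignments=pd.Series(labels, index=table.index),
        froh=froh, het_genomewide=het_gw, het_outbred=het_out, fit=fit,
    )


def roh_bed(table: pd.DataFrame, callset: RoHCallset) -> str:
    """RoH track as BED text, adjacent RoH windows merged."""
    lines = []
    cur = None  # (contig, start, end)
    for (_, row), label in zip(table.iterrows(), callset.assignments):
        if label != "RoH":
            if cur:
                lines.append(f"{cur[0]}\t{cur[1]}\t{cur[2]}")
                cur = None
            continue
        if cur and cur[0] == row.contig and cur[2] == row.start:
            cur = (cur[0], cur[1], row.end)
        else:
            if cur:
                lines.append(f"{cur[0]}\t{cur[1]}\t{cur[2]}")
            cur = (row.contig, row.start, row.end)
    if cur:
        lines.append(f"{cur[0]}\t{cur[1]}\t{cur[2]}")
    return "\n".join(lines) + ("\n" if lines else "")
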