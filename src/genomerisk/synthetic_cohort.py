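"""Synthetic cohorts with the statistical structure the analysis assumes.

Every downstream stage is testable without external data: this module
generates pure-birth phylogenies, Brownian-motion-correlated species
trait tables (with configurable Ne->load and Ne->threat effect sizes),
toy genome bundles (reference/ancestral FASTA, heterozygous VCF,
callable mask, conservation-score track, gene models, knockout-viability
table), bimodal windowed-heterozygosity tables, and PSMC-format text
whose parse+rescale round trip recovers the input trajectory.

All outputs are bit-reproducible given (params, seed).
"""

from __future__ import annotations

import itertools
import os
import textwrap
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.special import expit

from .demography import Epoch, NeTrajectory
from .errors import InvalidParameterError
from .phylo_stats import IUCN_ORDER, PhyloCovariance, tree_to_covariance

BASES = np.array(list("ACGT"))
STOP_CODONS = ("TAA", "TAG", "TGA")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: canonical genome-wide summary statistic columns, one row per species
SUMMARY_COLUMNS = (
    "ne_harmonic", "froh", "het_genomewide", "het_outbred",
    "prop_conserved_subs", "phylop_kurtosis",
    "prop_missense_fixed", "prop_missense_het", "prop_lof_het",
    "prop_missense_fixed_lethal", "prop_missense_fixed_viable",
    "prop_missense_het_lethal", "prop_missense_het_viable",
)


# ---------------------------------------------------------------------------
# cohort parameters


@dataclass(frozen=True)
class CohortParams:
    """Study conditions for a simulated cohort.

    Effect sizes act on standardized latent scales: ``beta_load_ne`` is
    the slope of each load proportion on log Ne (per log-unit);
    ``beta_threat_ne`` and ``beta_threat_eco`` are correlations of the
    threat liability with the standardized log-Ne and latent ecological
    factors. Defaults are chosen so smaller-Ne species carry
    proportionally more missense load and higher threat probability, and
    ecological variables out-predict genomic ones.
    """

    n_species: int = 240
    birth_rate: float = 1.0
    ne_log_mean: float = float(np.log(25_000.0))
    ne_log_sd: float = 0.6
    beta_load_ne: float = -0.05
    beta_threat_ne: float = -0.45
    beta_threat_eco: float = 0.6
    lambda_signal: float = 0.5
    threat_prevalence: float = 0.35
    missing_rate: float = 0.1
    n_eco: int = 39
    n_orders: int = 12
    trait_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise InvalidParameterError(f"n_species must be >= 2, got {self.n_species}")
        if not 0.0 <= self.lambda_signal <= 1.0:
            raise InvalidParameterError(f"lambda_signal must lie in [0,1], got {self.lambda_signal}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidParameterError(f"missing_rate must lie in [0,1), got {self.missing_rate}")
        if not 0.0 < self.threat_prevalence < 1.0:
            raise InvalidParameterError(f"threat_prevalence must lie in (0,1), got {self.threat_prevalence}")
        if self.birth_rate <= 0:
            raise InvalidParameterError(f"birth_rate must be > 0, got {self.birth_rate}")


# ---------------------------------------------------------------------------
# pure-birth (Yule) trees


def generate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Simulate a pure-birth ultrametric tree with ``n_species`` tips.

    Lineages split at rate ``birth_rate`` each; after the cohort reaches
    ``n_species`` lineages a final exponential stretch separates the last
    split from the present, so every terminal branch is strictly
    positive. Tips are labeled sp0001..spNNNN in traversal order.
    """
    if n_species < 2:
        raise InvalidParameterError(f"n_species must be >= 2, got {n_species}")
    if birth_rate <= 0:
        raise InvalidParameterError(f"birth_rate must be > 0, got {birth_rate}")
    rng = np.random.default_rng(seed)
    # node = [birth_time, end_time, [children]]
    root = [0.0, None, []]
    active = [root]
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        parent[1] = t
        kids = [[t, None, []], [t, None, []]]
        parent[2].extend(kids)
        active.extend(kids)
    t += rng.exponential(1.0 / (birth_rate * n_species))
    for tip in active:
        tip[1] = t

    counter = [0]

    def newick(node) -> str:
        bl = node[1] - node[0]
        if not node[2]:
            counter[0] += 1
            return f"sp{counter[0]:04d}:{bl:.12f}"
        inner = ",".join(newick(ch) for ch in node[2])
        return f"({inner}):{bl:.12f}"

    # root the tree at the first split: the stem before it is shared by all
    # tips and carries no contrast information
    nwk = "(" + ",".join(newick(ch) for ch in root[2]) + ");"
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    tree.is_rooted = True
    return tree


def clade_partition(tree: dendropy.Tree, k: int) -> dict[str, int]:
    """Partition tips into ~k monophyletic blocks (whole clades).

    Maximal subtrees with at most ceil(n/k) tips form the blocks; blocks
    are then binned into k groups in traversal order, so each group is a
    union of adjacent clades.
    """
    tips = tree.leaf_nodes()
    n = len(tips)
    target = int(np.ceil(n / k))
    counts: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            counts[id(node)] = 1
        else:
            counts[id(node)] = sum(counts[id(ch)] for ch in node.child_nodes())

    blocks: list[list[str]] = []

    def descend(node):
        if counts[id(node)] <= target or node.is_leaf():
            blocks.append([l.taxon.label for l in node.leaf_iter()])
            return
        for ch in node.child_nodes():
            descend(ch)

    descend(tree.seed_node)
    nb = len(blocks)
    out: dict[str, int] = {}
    for b, labels in enumerate(blocks):
        group = min(b * k // nb, k - 1)
        for lab in labels:
            out[lab] = group
    return out


# ---------------------------------------------------------------------------
# species trait tables


@dataclass(frozen=True)
class CohortTables:
    """Simulated cohort: feature table plus retained generating truth."""

    features: pd.DataFrame  # indexed by species label
    truth: dict
    tree: dendropy.Tree


def simulate_species_traits(tree: dendropy.Tree, params: CohortParams) -> CohortTables:
    """Evolve the 13 genome-wide summary statistics plus ecology on a tree.

    log Ne follows Brownian motion scaled by ``lambda_signal`` (at 0 tip
    values are i.i.d.); each load proportion is intercept +
    beta_load_ne * logNe + BM noise, clipped to (0, 1); threat liability
    combines the standardized log-Ne and a latent ecological factor and
    is cut by quantiles into IUCN categories at the stated prevalence.
    Diet and taxonomic order are assigned to whole clades; ecological
    columns carry loadings on the latent factor and missing-at-random
    cells.
    """
    cov = tree_to_covariance(tree)
    labels = list(cov.labels)
    n = len(labels)
    if n < 2:
        raise InvalidParameterError("tree must have >= 2 tips")
    rng = np.random.default_rng(params.seed)
    cn = cov.normalized()
    v = params.lambda_signal * cn + (1.0 - params.lambda_signal) * np.diag(np.diag(cn))
    chol = np.linalg.cholesky(v + np.eye(n) * 1e-12)

    def bm() -> np.ndarray:
        return chol @ rng.standard_normal(n)

    z_ne = bm()
    log_ne = params.ne_log_mean + params.ne_log_sd * z_ne
    centered = log_ne - params.ne_log_mean
    s = params.trait_noise_sd
    b = params.beta_load_ne
    eps = 1e-4

    def prop(intercept, slope=b, noise=s):
        return np.clip(intercept + slope * centered + noise * bm(), eps, 1 - eps)

    froh = expit(-1.5 - 0.8 * z_ne + 0.5 * bm())
    het_gw = np.exp(-6.2 + 0.5 * z_ne + 0.2 * bm())
    feats = pd.DataFrame(index=pd.Index(labels, name="species"))
    feats["ne_harmonic"] = np.exp(log_ne)
    feats["froh"] = froh
    feats["het_genomewide"] = het_gw
    feats["het_outbred"] = het_gw / (1.0 - 0.5 * froh)
    feats["prop_conserved_subs"] = prop(0.30)
    feats["phylop_kurtosis"] = 6.0 + 0.5 * z_ne + 0.3 * bm()
    feats["prop_missense_fixed"] = prop(0.50)
    feats["prop_missense_het"] = prop(0.50)
    feats["prop_lof_het"] = prop(0.05, slope=0.0, noise=0.01)
    feats["prop_missense_fixed_lethal"] = prop(0.35)
    feats["prop_missense_fixed_viable"] = prop(0.55)
    feats["prop_missense_het_lethal"] = prop(0.35)
    feats["prop_missense_het_viable"] = prop(0.55)

    # latent ecological factor and threat liability
    z_eco = bm()
    resid = np.sqrt(max(0.05, 1.0 - params.beta_threat_ne**2 - params.beta_threat_eco**2))
    liability = params.beta_threat_ne * z_ne + params.beta_threat_eco * z_eco + resid * bm()

    n_threat = int(round(params.threat_prevalence * n))
    n_threat = min(max(n_threat, 1), n - 1)
    order_liab = np.argsort(liability)
    iucn = np.array(["LC"] * n, dtype=object)
    threatened_idx = order_liab[-n_threat:]
    # split threatened mass into NT/VU/EN/CR (0.4/0.3/0.2/0.1 of threatened)
    cuts = np.cumsum([0.4, 0.3, 0.2])
    bounds = (cuts * n_threat).astype(int)
    cats = np.empty(n_threat, dtype=object)
    cats[: bounds[0]] = "NT"
    cats[bounds[0]: bounds[1]] = "VU"
    cats[bounds[1]: bounds[2]] = "EN"
    cats[bounds[2]:] = "CR"
    iucn[threatened_idx] = cats
    feats["iucn"] = iucn
    feats["threatened"] = [c != "LC" for c in iucn]

    orders = clade_partition(tree, params.n_orders)
    feats["tax_order"] = [f"order_{orders[l]:02d}" for l in labels]
    diets = clade_partition(tree, 6)
    diet_names = ("carnivore", "herbivore", "omnivore")
    feats["diet"] = [diet_names[diets[l] % 3] for l in labels]

    loadings = rng.uniform(0.3, 0.8, size=params.n_eco)
    eco = {}
    for j in range(params.n_eco):
        col = loadings[j] * z_eco + np.sqrt(1 - loadings[j] ** 2) * rng.standard_normal(n)
        miss = rng.random(n) < params.missing_rate
        col = col.astype(float)
        col[miss] = np.nan
        eco[f"eco_{j+1:02d}"] = col
    feats = pd.concat([feats, pd.DataFrame(eco, index=feats.index)], axis=1)

    truth = {
        "z_ne": pd.Series(z_ne, index=feats.index),
        "z_eco": pd.Series(z_eco, index=feats.index),
        "liability": pd.Series(liability, index=feats.index),
        "log_ne": pd.Series(log_ne, index=feats.index),
        "eco_loadings": loadings,
        "params": params,
    }
    return CohortTables(features=feats, truth=truth, tree=tree)


# ---------------------------------------------------------------------------
# toy genome bundles


@dataclass(frozen=True)
class GenomeParams:
    """Knobs for a toy genome with planted, recoverable structure."""

    contig_lengths: tuple[int, ...] = (100_000, 100_000)
    substitution_rate: float = 1e-3
    het_rate: float = 2e-3
    roh_het_factor: float = 0.1
    f_roh: float = 0.2
    n_genes: int = 20
    cds_codons: int = 100  # sense codons; total CDS = 3*(cds_codons+2)
    frac_missense: float = 0.5
    frac_synonymous: float = 0.45
    frac_lof: float = 0.05
    n_coding_subs: int | None = None   # None -> Poisson(rate * coding length)
    n_coding_hets: int | None = None
    conserved_fraction: float = 0.3
    callable_fraction: float = 0.95
    n_ambiguous: int = 10

    def __post_init__(self) -> None:
        for L in self.contig_lengths:
            if L < 1000:
                raise InvalidParameterError(f"contig lengths must be >= 1 kb, got {L}")
        for name in ("substitution_rate", "het_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 0.1:
                raise InvalidParameterError(f"{name} must lie in [0, 0.1], got {r}")
        tot = self.frac_missense + self.frac_synonymous + self.frac_lof
        if abs(tot - 1.0) > 1e-9:
            raise InvalidParameterError(f"consequence fractions must sum to 1, got {tot}")
        if not 0.0 <= self.f_roh <= 1.0:
            raise InvalidParameterError(f"f_roh must lie in [0,1], got {self.f_roh}")


@dataclass(frozen=True)
class ToyGenomeBundle:
    reference: str
    ancestral: str
    variants: str
    callable_mask: str
    phylop_track: str
    gene_models: str
    impc_table: str
    truth: "GenomeTruth"


@dataclass(frozen=True)
class GenomeTruth:
    """Planted structure retained for generator/consumer round trips."""

    substitutions: pd.DataFrame  # contig, pos, ancestral, derived, category
    het_variants: pd.DataFrame   # contig, pos, ref, alt, category
    site_scores: pd.DataFrame    # contig, pos, score, conserved
    callable_intervals: dict[str, np.ndarray]
    roh_tracts: dict[str, np.ndarray]
    gene_classes: dict[str, str]
    contig_lengths: dict[str, int]
    n_ambiguous: int

    def window_table(self, window_size: int, min_callable_fraction: float = 0.5) -> pd.DataFrame:
        """Expected per-window het/callable counts from the planted data."""
        rows = []
        hets = self.het_variants
        for contig, length in self.contig_lengths.items():
            ivs = self.callable_intervals[contig]
            hp = hets.loc[hets.contig == contig, "pos"].to_numpy()
            for wstart in range(0, length, window_size):
                wend = min(wstart + window_size, length)
                lo = np.clip(ivs[:, 0], wstart, wend)
                hi = np.clip(ivs[:, 1], wstart, wend)
                n_call = int(np.maximum(hi - lo, 0).sum())
                n_het = int(((hp >= wstart) & (hp < wend)).sum())
                ratio = n_het / n_call if n_call else np.nan
                rows.append((contig, wstart, wend, n_het, n_call, ratio,
                             n_call >= min_callable_fraction * (wend - wstart)))
        return pd.DataFrame(rows, columns=[
            "contig", "start", "end", "n_het", "n_callable", "ratio", "assessed"])


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _candidate_changes(codon: str) -> dict[str, list[tuple[int, str]]]:
    """Single-base changes of a codon grouped by consequence category.

    Categories here: synonymous, missense, stop_gain (change creates a
    stop). Changes touching ambiguous outcomes (from a stop codon) are
    not produced because callers never pass stop/start codons.
    """
    aa0 = _translate(codon)
    out: dict[str, list[tuple[int, str]]] = {"synonymous": [], "missense": [], "stop_gain": []}
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            aa1 = _translate(mut)
            if aa1 == "*":
                out["stop_gain"].append((i, b))
            elif aa1 == aa0:
                out["synonymous"].append((i, b))
            else:
                out["missense"].append((i, b))
    return out


def _write_fasta(path: str, seqs: dict[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for name, arr in seqs.items():
            fh.write(f">{name}\n")
            s = "".join(arr)
            fh.write("\n".join(textwrap.wrap(s, 60)) + "\n")


def _runs_true(mask: np.ndarray) -> np.ndarray:
    """(n, 2) start/end intervals of True runs in a boolean array."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return np.column_stack([starts, ends])


def simulate_genome(params: GenomeParams, out_dir: str, seed: int = 0) -> ToyGenomeBundle:
    """Write a seven-file toy genome bundle with planted, known structure.

    Substitutions are placed by a Poisson process at the target rate
    (ancestral carries the older base, the reference the derived one);
    coding variants are planted with controllable missense/synonymous/
    stop-gained fractions; conservation scores come from a two-component
    mixture (background N(0,1), conserved N(4,1)) with a known conserved
    fraction; heterozygous variants are depressed by ``roh_het_factor``
    inside planted RoH tracts.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    contigs = {f"ctg{i+1}": int(L) for i, L in enumerate(params.contig_lengths)}

    ref: dict[str, np.ndarray] = {}
    for name, L in contigs.items():
        ref[name] = rng.choice(BASES, size=L)

    # --- gene placement ------------------------------------------------
    cds_len = 3 * (params.cds_codons + 2)
    sense = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
             if c not in STOP_CODONS and c != "ATG"]
    genes: list[dict] = []
    per_contig = np.array_split(np.arange(params.n_genes), len(contigs))
    coding_mask = {name: np.zeros(L, dtype=bool) for name, L in contigs.items()}
    for (name, L), idxs in zip(contigs.items(), per_contig):
        k = len(idxs)
        if k == 0:
            continue
        margin = 500
        spacing = (L - 2 * margin) // max(k, 1)
        if spacing <= cds_len + 10:
            raise InvalidParameterError(
                f"contig {name} too short for {k} genes of CDS length {cds_len}")
        for j, gi in enumerate(idxs):
            start = margin + j * spacing
            strand = "+" if rng.random() < 0.5 else "-"
            body = "".join(rng.choice(sense) for _ in range(params.cds_codons))
            gene_seq = "ATG" + body + str(rng.choice(STOP_CODONS))
            if strand == "-":
                ins = "".join(COMPLEMENT[b] for b in reversed(gene_seq))
            else:
                ins = gene_seq
            ref[name][start:start + cds_len] = list(ins)
            coding_mask[name][start:start + cds_len] = True
            genes.append({
                "gene_id": f"g{gi+1:04d}", "contig": name, "strand": strand,
                "start": start, "end": start + cds_len, "seq": gene_seq,
            })

    # --- callable mask (gaps only in noncoding sequence) ----------------
    callable_mask = {name: np.ones(L, dtype=bool) for name, L in contigs.items()}
    gap_len = 200
    for name, L in contigs.items():
        target_gap = int((1.0 - params.callable_fraction) * L)
        placed = 0
        attempts = 0
        while placed < target_gap and attempts < 10_000:
            attempts += 1
            s = int(rng.integers(0, L - gap_len))
            sl = slice(s, s + gap_len)
            if coding_mask[name][sl].any() or not callable_mask[name][sl].all():
                continue
            callable_mask[name][sl] = False
            placed += gap_len

    # --- RoH tracts -----------------------------------------------------
    roh_mask = {name: np.zeros(L, dtype=bool) for name, L in contigs.items()}
    for name, L in contigs.items():
        tract = int(params.f_roh * L)
        if tract > 0:
            s = int(rng.integers(0, L - tract + 1))
            roh_mask[name][s:s + tract] = True

    anc = {name: ref[name].copy() for name in contigs}
    used = {name: coding_mask[name].copy() for name in contigs}  # sites already edited/reserved

    sub_rows: list[tuple] = []
    het_rows: list[tuple] = []

    # --- noncoding substitutions ---------------------------------------
    for name, L in contigs.items():
        cand = np.flatnonzero(~coding_mask[name])
        k = rng.poisson(params.substitution_rate * cand.size)
        k = min(k, cand.size)
        pos = rng.choice(cand, size=k, replace=False)
        for p in np.sort(pos):
            der = ref[name][p]
            a = rng.choice([b for b in "ACGT" if b != der])
            anc[name][p] = a
            used[name][p] = True
            sub_rows.append((name, int(p), a, der, "noncoding", "fixed"))

    # --- coding variants with controlled consequence fractions ----------
    coding_len = params.n_genes * cds_len
    fracs = np.array([params.frac_synonymous, params.frac_missense, params.frac_lof])
    cat_names = ["synonymous", "missense", "LOF"]

    def plant_coding(n_total: int, kind: str):
        """kind='sub' edits the ancestral (or ref for LOF); 'het' records a VCF row."""
        counts = rng.multinomial(n_total, fracs)
        for cat, cnt in zip(cat_names, counts):
            placed = 0
            attempts = 0
            while placed < cnt and attempts < 100 * cnt + 1000:
                attempts += 1
                g = genes[int(rng.integers(len(genes)))]
                ci = int(rng.integers(1, params.cds_codons + 1))  # interior sense codons
                if (g["gene_id"], ci) in planted_codons:
                    continue  # one variant per codon keeps contexts independent
                codon = g["seq"][3 * ci: 3 * ci + 3]
                cands = _candidate_changes(codon)
                key = "stop_gain" if cat == "LOF" else cat
                if not cands[key]:
                    continue
                within, newb = cands[key][int(rng.integers(len(cands[key])))]
                cds_pos = 3 * ci + within
                # map CDS coordinate to genome coordinate and plus-strand base
                if g["strand"] == "+":
                    gpos = g["start"] + cds_pos
                    genome_new = newb
                else:
                    gpos = g["end"] - 1 - cds_pos
                    genome_new = COMPLEMENT[newb]
                name = g["contig"]
                planted_codons.add((g["gene_id"], ci))
                old = ref[name][gpos]
                if kind == "sub":
                    if cat == "LOF":
                        # derived (reference) allele creates the stop: edit ref
                        ref[name][gpos] = genome_new
                        anc[name][gpos] = old
                        sub_rows.append((name, int(gpos), old, genome_new, "LOF", "fixed"))
                    else:
                        # ancestral carries the alternative sense base
                        anc[name][gpos] = genome_new
                        sub_rows.append((name, int(gpos), genome_new, old, cat, "fixed"))
                else:
                    het_rows.append((name, int(gpos), old, genome_new, cat))
                placed += 1

    planted_codons: set[tuple[str, int]] = set()
    n_csub = params.n_coding_subs
    if n_csub is None:
        n_csub = rng.poisson(params.substitution_rate * coding_len)
    plant_coding(n_csub, "sub")
    n_chet = params.n_coding_hets
    if n_chet is None:
        n_chet = rng.poisson(params.het_rate * coding_len)
    plant_coding(n_chet, "het")

    # --- noncoding heterozygous variants (RoH-aware, callable only) -----
    for name, L in contigs.items():
        free = ~coding_mask[name] & callable_mask[name] & ~used[name]
        for in_roh, rate in ((False, params.het_rate),
                             (True, params.het_rate * params.roh_het_factor)):
            cand = np.flatnonzero(free & (roh_mask[name] == in_roh))
            k = min(rng.poisson(rate * cand.size), cand.size)
            pos = rng.choice(cand, size=k, replace=False)
            for p in pos:
                rb = ref[name][p]
                alt = rng.choice([b for b in "ACGT" if b != rb])
                het_rows.append((name, int(p), rb, alt, "noncoding"))
                used[name][p] = True

    # --- ambiguity codes in the ancestral --------------------------------
    n_amb = 0
    for name in contigs:
        free = np.flatnonzero(~coding_mask[name] & ~used[name])
        take = min(params.n_ambiguous // len(contigs) + 1, free.size)
        pos = rng.choice(free, size=take, replace=False)
        for p in pos:
            if n_amb >= params.n_ambiguous:
                break
            anc[name][p] = "N"
            used[name][p] = True
            n_amb += 1

    subs = pd.DataFrame(sub_rows, columns=["contig", "pos", "ancestral", "derived",
                                           "category", "zygosity"])
    subs = subs.sort_values(["contig", "pos"]).reset_index(drop=True)
    hets = pd.DataFrame(het_rows, columns=["contig", "pos", "ref", "alt", "category"])
    hets = hets.sort_values(["contig", "pos"]).reset_index(drop=True)

    # --- conservation scores at variant sites ----------------------------
    sites = pd.concat([
        subs[["contig", "pos"]], hets[["contig", "pos"]]
    ]).drop_duplicates().sort_values(["contig", "pos"]).reset_index(drop=True)
    conserved = rng.random(len(sites)) < params.conserved_fraction
    scores = np.where(conserved, rng.normal(4.0, 1.0, len(sites)),
                      rng.normal(0.0, 1.0, len(sites)))
    site_scores = sites.assign(score=scores, conserved=conserved)

    # --- write the seven files -------------------------------------------
    paths = {k: os.path.join(out_dir, v) for k, v in {
        "reference": "reference.fa", "ancestral": "ancestral.fa",
        "variants": "variants.vcf", "callable_mask": "callable.bed",
        "phylop_track": "phylop.bed", "gene_models": "genes.gff3",
        "impc_table": "impc.tsv",
    }.items()}
    _write_fasta(paths["reference"], ref)
    _write_fasta(paths["ancestral"], anc)

    with open(paths["variants"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, L in contigs.items():
            fh.write(f"##contig=<ID={name},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for r in hets.itertuples(index=False):
            fh.write(f"{r.contig}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t0/1\n")

    callable_ivs = {}
    with open(paths["callable_mask"], "w") as fh:
        for name in contigs:
            ivs = _runs_true(callable_mask[name])
            callable_ivs[name] = ivs
            for s, e in ivs:
                fh.write(f"{name}\t{s}\t{e}\n")

    with open(paths["phylop_track"], "w") as fh:
        for r in site_scores.itertuples(index=False):
            fh.write(f"{r.contig}\t{r.pos}\t{r.pos + 1}\t{r.score:.6f}\n")

    with open(paths["gene_models"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            a = {"s": g["start"] + 1, "e": g["end"], "st": g["strand"], "id": g["gene_id"]}
            fh.write(f"{g['contig']}\tgenomerisk\tgene\t{a['s']}\t{a['e']}\t.\t{a['st']}\t.\tID={a['id']}\n")
            fh.write(f"{g['contig']}\tgenomerisk\tmRNA\t{a['s']}\t{a['e']}\t.\t{a['st']}\t.\tID={a['id']}.t1;Parent={a['id']}\n")
            fh.write(f"{g['contig']}\tgenomerisk\tCDS\t{a['s']}\t{a['e']}\t.\t{a['st']}\t0\tID={a['id']}.cds;Parent={a['id']}.t1\n")

    classes = rng.choice(["lethal", "subviable", "viable"], size=len(genes), p=[0.3, 0.2, 0.5])
    gene_classes = {g["gene_id"]: c for g, c in zip(genes, classes)}
    with open(paths["impc_table"], "w") as fh:
        fh.write("gene_id\tclass\n")
        for gid, c in gene_classes.items():
            fh.write(f"{gid}\t{c}\n")

    truth = GenomeTruth(
        substitutions=subs, het_variants=hets, site_scores=site_scores,
        callable_intervals=callable_ivs,
        roh_tracts={n: _runs_true(roh_mask[n]) for n in contigs},
        gene_classes=gene_classes,
        contig_lengths=contigs, n_ambiguous=n_amb,
    )
    return ToyGenomeBundle(truth=truth, **paths)


# ---------------------------------------------------------------------------
# windowed heterozygosity tables


@dataclass(frozen=True)
class WindowHetSim:
    table: pd.DataFrame
    labels: np.ndarray  # True where the window was drawn from the RoH component


def simulate_window_het(
    n_windows: int,
    f_roh: float,
    mu_roh: float,
    mu_bg: float,
    seed: int = 0,
    window_size: int = 50_000,
    callable_per_window: int = 45_000,
) -> WindowHetSim:
    """Draw a bimodal windowed-heterozygosity table with retained labels.

    Each window is RoH with probability ``f_roh``; het counts are
    binomial from ``callable_per_window`` sites at the component rate.
    """
    if not 0.0 <= f_roh <= 1.0:
        raise InvalidParameterError(f"f_roh must lie in [0,1], got {f_roh}")
    if not 0.0 <= mu_roh < mu_bg:
        raise InvalidParameterError(
            f"need 0 <= mu_roh < mu_bg, got mu_roh={mu_roh}, mu_bg={mu_bg}")
    rng = np.random.default_rng(seed)
    labels = rng.random(n_windows) < f_roh
    rates = np.where(labels, mu_roh, mu_bg)
    n_het = rng.binomial(callable_per_window, rates)
    starts = np.arange(n_windows) * window_size
    table = pd.DataFrame({
        "contig": "sim", "start": starts, "end": starts + window_size,
        "n_het": n_het, "n_callable": callable_per_window,
        "ratio": n_het / callable_per_window, "assessed": True,
    })
    return WindowHetSim(table=table, labels=labels)


# ---------------------------------------------------------------------------
# PSMC-format text


def simulate_psmc_output(
    trajectory: NeTrajectory,
    mu: float,
    gen_time: float,
    bin_size: int = 100,
    n_iterations: int = 2,
) -> str:
    """Emit PSMC-format text whose parse + rescale round trip is the input.

    This is the exact inverse of the rescaling arithmetic: N0 is the
    youngest epoch's Ne, theta0 = 4*mu*s*N0, lambda_k = Ne_k/N0 and
    t_k = start_years_k / (2*N0*g). A terminal open-ended RS entry marks
    the oldest epoch's end (dropped again on rescale). Several iteration
    blocks are written; only the last is authoritative.
    """
    if mu <= 0 or gen_time <= 0:
        raise InvalidParameterError(
            f"mu and gen_time must be > 0, got mu={mu}, gen_time={gen_time}")
    n0 = trajectory.epochs[0].ne
    theta0 = 4.0 * mu * bin_size * n0
    lines = []

    def block(scale: float):
        lines.append("RD\t0")
        lines.append("LK\t-123456.789")
        lines.append(f"TR\t{theta0 * scale:.12g}\t{theta0 * scale / 5:.12g}")
        for k, ep in enumerate(trajectory.epochs):
            t_k = ep.start_years / (2.0 * n0 * gen_time)
            lam = ep.ne / n0
            lines.append(f"RS\t{k}\t{t_k:.12g}\t{lam:.12g}\t0\t0\t0")
        last = trajectory.epochs[-1]
        t_end = last.end_years / (2.0 * n0 * gen_time)
        lines.append(f"RS\t{len(trajectory.epochs)}\t{t_end:.12g}\t{last.ne / n0:.12g}\t0\t0\t0")
        lines.append("PA\t4+25*2+4+6 0")
        lines.append("//")

    # earlier iterations carry perturbed parameters and must be ignored
    for i in range(n_iterations - 1):
        block(scale=1.0 + 0.5 * (i + 1))
    block(scale=1.0)
    return "\n".join(lines) + "\n"


def random_trajectory(
    n_epochs: int,
    seed: int = 0,
    gen_time: float = 5.0,
    mu: float = 1e-8,
) -> NeTrajectory:
    """A random piecewise-constant Ne history for round-trip sweeps."""
    rng = np.random.default_rng(seed)
    bounds = np.concatenate([[0.0], np.sort(rng.uniform(1e3, 2e6, n_epochs))])
    nes = rng.uniform(1e3, 1e5, n_epochs)
    epochs = tuple(
        Epoch(start_years=float(bounds[i]), end_years=float(bounds[i + 1]), ne=float(nes[i]))
        for i in range(n_epochs)
    )
    return NeTrajectory(epochs=epochs, gen_time=gen_time, mu=mu)
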