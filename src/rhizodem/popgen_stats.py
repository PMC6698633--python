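"""Diversity, neutrality, and selection statistics for MLST alignments.

Implements the classical per-locus summaries for haploid sequence samples:
segregating sites, nucleotide diversity π, Watterson's θ_w, Tajima's D,
Fu's F_s (via the Ewens sampling formula with unsigned Stirling numbers,
computed in log space so samples of hundreds of strains are safe), the
Nei–Gojobori counts of synonymous/nonsynonymous polymorphism and diversity
(p_N/p_S, d_N/d_S), haplotype diversity, and Hudson's pairwise F_ST.

Significance of Tajima's D and Fu's F_s is assessed by neutral coalescent
simulation conditional on the observed sample size and number of segregating
sites: mutations are placed on a standard Kingman genealogy in proportion to
branch length.  Reported p-values are the lower-tail fractions
P(stat_sim <= stat_obs).

All distance-based statistics apply the complete-deletion missing-data
policy (columns containing N or - are excluded) via ``LocusAlignment.masked``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

from .mlst_io import HaplotypeTable, LocusAlignment, collapse_haplotypes

__all__ = [
    "DiversitySummary",
    "pairwise_difference_matrix",
    "segregating_sites",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "fus_fs",
    "fs_from_pi_k",
    "ewens_log_pk",
    "pn_ps_dn_ds",
    "haplotype_diversity",
    "hudson_fst",
    "diversity_summary",
]

_BASES = b"ACGT"


# ---------------------------------------------------------------------------
# pairwise differences and basic estimators
# ---------------------------------------------------------------------------

def _encoded(aln: LocusAlignment) -> np.ndarray:
    """(n, L) int8 codes over retained columns (complete deletion)."""
    arr = aln.masked().to_array()
    codes = np.zeros(arr.shape, dtype=np.int8)
    for i, b in enumerate(_BASES):
        codes[arr == bytes([b])] = i
    return codes


def pairwise_difference_matrix(aln: LocusAlignment) -> np.ndarray:
    """Hamming distances over retained columns; symmetric, zero diagonal."""
    if aln.n < 2:
        raise ValueError("need >= 2 sequences")
    codes = _encoded(aln)
    n, L = codes.shape
    # one-hot trick: matches_ij = sum_sites [codes_i == codes_j]
    onehot = np.zeros((n, L, 4), dtype=np.float32)
    idx = np.arange(L)
    for i in range(n):
        onehot[i, idx, codes[i]] = 1.0
    flat = onehot.reshape(n, 4 * L)
    matches = flat @ flat.T
    diffs = np.rint(L - matches).astype(np.int64)
    np.fill_diagonal(diffs, 0)
    return diffs


def segregating_sites(aln: LocusAlignment) -> int:
    codes = _encoded(aln)
    return int(np.sum(np.any(codes != codes[0], axis=0)))


def nucleotide_diversity(aln: LocusAlignment) -> tuple[float, float]:
    """Mean pairwise differences, absolute and per retained site."""
    d = pairwise_difference_matrix(aln)
    n = d.shape[0]
    pi_abs = d[np.triu_indices(n, 1)].mean()
    L = aln.masked().length
    return float(pi_abs), float(pi_abs / L) if L else 0.0


def harmonic(m: int, power: int = 1) -> float:
    return float(sum(1.0 / i ** power for i in range(1, m + 1)))


def watterson_theta(aln: LocusAlignment) -> tuple[float, float]:
    """S / a_{n-1}, absolute and per retained site."""
    if aln.n < 2:
        raise ValueError("need >= 2 sequences")
    S = segregating_sites(aln)
    theta = S / harmonic(aln.n - 1)
    L = aln.masked().length
    return float(theta), float(theta / L) if L else 0.0


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return e1, e2


def _d_from_pi_s(pi: float, S: int, n: int) -> float:
    e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    return (pi - S / harmonic(n - 1)) / math.sqrt(var)


def tajimas_d(aln: LocusAlignment, n_reps: int = 0, seed: int | None = None):
    """Tajima's D; optionally a simulated lower-tail p-value.

    Returns ``(D, p)``; ``p`` is None when ``n_reps`` is 0, and both are
    None (not computable) for monomorphic alignments.
    """
    if aln.n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    S = segregating_sites(aln)
    if S == 0:
        return None, None
    pi_abs, _ = nucleotide_diversity(aln)
    d_obs = _d_from_pi_s(pi_abs, S, aln.n)
    if n_reps <= 0:
        return d_obs, None
    rng = np.random.default_rng(seed)
    sims = np.array([_d_from_pi_s(_sim_pi_k(aln.n, S, rng)[0], S, aln.n)
                     for _ in range(n_reps)])
    p = float(np.mean(sims <= d_obs))
    return d_obs, p


# ---------------------------------------------------------------------------
# Fu's Fs (Ewens sampling formula)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _log_stirling_first(n: int) -> tuple[float, ...]:
    """log unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    ls = np.full(n + 1, -np.inf)
    ls[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        # |s(m,k)| = (m-1)|s(m-1,k)| + |s(m-1,k-1)|
        with np.errstate(divide="ignore"):
            grown = ls + (math.log(m - 1) if m > 1 else -np.inf)
        new[1:] = np.logaddexp(grown[1:], ls[:-1])
        if m == 1:
            new[1] = 0.0
        ls = new
    return tuple(ls)


def ewens_log_pk(n: int, theta: float) -> np.ndarray:
    """log P(K = k | theta, n) for k = 1..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    ls = np.array(_log_stirling_first(n)[1:])  # k = 1..n
    k = np.arange(1, n + 1)
    log_rising = sum(math.log(theta + i) for i in range(n))
    return ls + k * math.log(theta) - log_rising


def fs_from_pi_k(pi: float, k_obs: int, n: int) -> float | None:
    """Fu's Fs = ln(S'/(1-S')) with S' = P(K >= k_obs | theta = pi).

    Returns None (undefined) when pi == 0 or S' degenerates to 1.
    """
    if pi <= 0:
        return None
    logs = ewens_log_pk(n, pi)
    from scipy.special import logsumexp
    log_sp = logsumexp(logs[k_obs - 1:])
    log_sp = min(log_sp, 0.0)
    sp = math.exp(log_sp)
    if sp >= 1.0:
        return None
    # log-space complement for extreme tails
    log_one_minus = logsumexp(logs[: k_obs - 1]) if k_obs > 1 else -math.inf
    if log_one_minus == -math.inf:
        return None
    return float(log_sp - log_one_minus)


def fus_fs(aln: LocusAlignment, n_reps: int = 0, seed: int | None = None):
    """Fu's Fs for an alignment; optional simulated lower-tail p-value.

    Haplotype count uses exact identity over retained columns.  Returns
    ``(Fs, p)``; Fs is None when π = 0.
    """
    pi_abs, _ = nucleotide_diversity(aln)
    k_obs = collapse_haplotypes(aln).k
    fs_obs = fs_from_pi_k(pi_abs, k_obs, aln.n)
    if fs_obs is None or n_reps <= 0:
        return fs_obs, None
    S = segregating_sites(aln)
    rng = np.random.default_rng(seed)
    sims = []
    for _ in range(n_reps):
        pi_sim, k_sim = _sim_pi_k(aln.n, S, rng)
        fs = fs_from_pi_k(pi_sim, k_sim, aln.n)
        sims.append(fs if fs is not None else np.inf)
    p = float(np.mean(np.asarray(sims) <= fs_obs))
    return fs_obs, p


# ---------------------------------------------------------------------------
# neutral conditional-on-S simulation (shared null for D and Fs)
# ---------------------------------------------------------------------------

def _sim_pi_k(n: int, S: int, rng: np.random.Generator) -> tuple[float, int]:
    """Simulate (pi, K) under the standard coalescent with S mutations
    dropped on the genealogy proportional to branch length."""
    # build Kingman genealogy: per-lineage leaf sets and branch lengths
    leafsets = [frozenset([i]) for i in range(n)]
    lengths = [0.0] * n
    finished: list[tuple[frozenset, float]] = []
    k = n
    t = 0.0
    while k > 1:
        rate = k * (k - 1) / 2.0
        dt = rng.exponential(1.0 / rate)
        lengths = [L + dt for L in lengths]
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        finished.append((leafsets[i], lengths[i]))
        finished.append((leafsets[j], lengths[j]))
        merged = leafsets[i] | leafsets[j]
        leafsets = [s for idx, s in enumerate(leafsets) if idx not in (i, j)] + [merged]
        lengths = [L for idx, L in enumerate(lengths) if idx not in (i, j)] + [0.0]
        k -= 1
        t += dt
    branches = [b for b in finished if 0 < len(b[0]) < n]
    if not branches:
        return 0.0, 1
    wts = np.array([b[1] for b in branches])
    probs = wts / wts.sum()
    picks = rng.choice(len(branches), size=S, p=probs)
    # pi from mutation subtended sizes; K from distinct mutation patterns
    pi = 0.0
    patterns: dict[int, list[int]] = {i: [] for i in range(n)}
    denom = n * (n - 1) / 2.0
    for m_idx, b_idx in enumerate(picks):
        leaves = branches[b_idx][0]
        c = len(leaves)
        pi += c * (n - c) / denom
        for leaf in leaves:
            patterns[leaf].append(m_idx)
    k_hap = len({tuple(sorted(v)) for v in patterns.values()})
    return pi, k_hap


# ---------------------------------------------------------------------------
# Nei–Gojobori p_N/p_S and d_N/d_S
# ---------------------------------------------------------------------------

_CODE = CodonTable.unambiguous_dna_by_id[1]


def _translate(codon: str) -> str | None:
    """Amino acid for a codon, '*' for stop, None if ambiguous."""
    if codon in _CODE.stop_codons:
        return "*"
    return _CODE.forward_table.get(codon)


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float] | None:
    """(synonymous, nonsynonymous) potential sites of a codon (NG86).

    Mutations to stop codons count as nonsynonymous.  Returns None for
    stop/ambiguous codons.
    """
    aa = _translate(codon)
    if aa is None or aa == "*":
        return None
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if _translate(mutant) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_pair_diffs(c1: str, c2: str) -> tuple[float, float] | None:
    """(syn, nonsyn) differences between two codons, averaged over all
    minimal mutational pathways; None if a pathway passes through a stop
    or a codon is a stop."""
    if _translate(c1) in (None, "*") or _translate(c2) in (None, "*"):
        return None
    import itertools
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    path_counts = []
    for order in itertools.permutations(positions):
        cur = c1
        syn = nsyn = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            a1, a2 = _translate(cur), _translate(nxt)
            if a2 == "*" or a1 == "*":
                ok = False
                break
            if a1 == a2:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if ok:
            path_counts.append((syn, nsyn))
    if not path_counts:
        # all pathways hit a stop: count every difference as nonsynonymous
        return 0.0, float(len(positions))
    syn = float(np.mean([p[0] for p in path_counts]))
    nsyn = float(np.mean([p[1] for p in path_counts]))
    return syn, nsyn


@dataclass
class SelectionSummary:
    p_n: float
    p_s: float
    pn_ps: float | None
    d_n: float
    d_s: float
    dn_ds: float | None
    n_sites_syn: float
    n_sites_nonsyn: float


def _codons_of(seq: str, frame: int) -> list[str]:
    usable = seq[frame:]
    return [usable[i:i + 3] for i in range(0, len(usable) - len(usable) % 3, 3)]


def pn_ps_dn_ds(aln: LocusAlignment, raw_counts: bool = False) -> SelectionSummary:
    """Nei–Gojobori synonymous/nonsynonymous polymorphism and diversity.

    Codons containing N/-/stop in any sequence are excluded (codon-wise
    complete deletion).  ``p_N``/``p_S`` count polymorphic sites (classified
    by substituting the two most frequent alleles into the consensus codon)
    normalized by potential-site totals unless ``raw_counts``.  ``d_N``/``d_S``
    are mean pairwise Nei–Gojobori proportions without multiple-hit
    correction (appropriate for the low within-population divergence here).
    """
    if not aln.coding:
        raise ValueError(f"locus {aln.name!r} is not coding")
    if aln.n < 2:
        raise ValueError("need >= 2 sequences")
    strains = aln.strains
    per_seq_codons = {sid: _codons_of(aln.sequences[sid], aln.frame) for sid in strains}
    n_codons = len(per_seq_codons[strains[0]])
    usable = []
    for ci in range(n_codons):
        col = [per_seq_codons[sid][ci] for sid in strains]
        if all(set(c) <= set("ACGT") and _translate(c) not in (None, "*") for c in col):
            usable.append(ci)
    if not usable:
        raise ValueError("no usable codon columns")
    n = len(strains)
    # potential sites, averaged over sequences
    syn_sites = np.zeros(n)
    nonsyn_sites = np.zeros(n)
    for i, sid in enumerate(strains):
        for ci in usable:
            s, ns = _codon_sites(per_seq_codons[sid][ci])
            syn_sites[i] += s
            nonsyn_sites[i] += ns
    S_sites = float(syn_sites.mean())
    N_sites = float(nonsyn_sites.mean())

    # polymorphic sites, classified in consensus context
    n_poly_syn = 0
    n_poly_nonsyn = 0
    for ci in usable:
        col = [per_seq_codons[sid][ci] for sid in strains]
        from collections import Counter
        consensus = "".join(Counter(c[p] for c in col).most_common(1)[0][0]
                            for p in range(3))
        for p in range(3):
            alleles = Counter(c[p] for c in col).most_common()
            if len(alleles) < 2:
                continue
            a, b = alleles[0][0], alleles[1][0]
            ca = consensus[:p] + a + consensus[p + 1:]
            cb = consensus[:p] + b + consensus[p + 1:]
            ta, tb = _translate(ca), _translate(cb)
            if ta == tb and ta not in (None, "*"):
                n_poly_syn += 1
            else:
                n_poly_nonsyn += 1

    if raw_counts:
        p_s, p_n = float(n_poly_syn), float(n_poly_nonsyn)
    else:
        p_s = n_poly_syn / S_sites if S_sites else 0.0
        p_n = n_poly_nonsyn / N_sites if N_sites else 0.0
    pn_ps = (p_n / p_s) if p_s > 0 else None

    # mean pairwise Nei–Gojobori proportions
    tot_syn = tot_nonsyn = 0.0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            sd = nd = 0.0
            for ci in usable:
                res = _codon_pair_diffs(per_seq_codons[strains[i]][ci],
                                        per_seq_codons[strains[j]][ci])
                if res is not None:
                    sd += res[0]
                    nd += res[1]
            tot_syn += sd
            tot_nonsyn += nd
            n_pairs += 1
    d_s = (tot_syn / n_pairs) / S_sites if S_sites else 0.0
    d_n = (tot_nonsyn / n_pairs) / N_sites if N_sites else 0.0
    dn_ds = (d_n / d_s) if d_s > 0 else None
    return SelectionSummary(p_n, p_s, pn_ps, d_n, d_s, dn_ds, S_sites, N_sites)


# ---------------------------------------------------------------------------
# haplotype diversity, Hudson F_ST
# ---------------------------------------------------------------------------

def haplotype_diversity(table: HaplotypeTable) -> float:
    """Hd = n/(n-1) * (1 - sum f_i^2)."""
    n = table.n
    if n < 2:
        raise ValueError("need >= 2 sequences")
    freqs = np.asarray(table.counts, dtype=float) / n
    return float(n / (n - 1) * (1.0 - np.sum(freqs ** 2)))


def hudson_fst(aln: LocusAlignment, groups: dict[str, list[str]]) -> dict[tuple[str, str], float | None]:
    """Pairwise Hudson F_ST = 1 - H_w/H_b between every pair of groups.

    H_w is the average of the two groups' mean within-group pairwise
    differences; H_b the mean between-group difference.  None when H_b = 0.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"group {g!r} has < 2 members")
    strains = aln.strains
    index = {s: i for i, s in enumerate(strains)}
    d = pairwise_difference_matrix(aln)
    out: dict[tuple[str, str], float | None] = {}
    names = list(groups)

    def mean_within(idx):
        sub = d[np.ix_(idx, idx)]
        m = len(idx)
        return sub[np.triu_indices(m, 1)].mean()

    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ia = [index[s] for s in groups[names[a]]]
            ib = [index[s] for s in groups[names[b]]]
            hw = 0.5 * (mean_within(ia) + mean_within(ib))
            hb = d[np.ix_(ia, ib)].mean()
            out[(names[a], names[b])] = None if hb == 0 else float(1.0 - hw / hb)
    return out


# ---------------------------------------------------------------------------
# per-locus summary
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    locus: str
    n: int
    S: int
    K: int
    Hd: float
    pi_abs: float
    pi_per_site: float
    theta_w_abs: float
    theta_w_per_site: float
    tajima_d: float | None
    tajima_p: float | None
    fu_fs: float | None
    fu_p: float | None
    selection: SelectionSummary | None = None


def diversity_summary(aln: LocusAlignment, n_reps: int = 1000,
                      seed: int | None = None) -> DiversitySummary:
    """Full per-locus diversity/neutrality summary row."""
    table = collapse_haplotypes(aln)
    pi_abs, pi_ps = nucleotide_diversity(aln)
    th_abs, th_ps = watterson_theta(aln)
    d, d_p = tajimas_d(aln, n_reps=n_reps, seed=seed) if aln.n >= 4 else (None, None)
    fs, fs_p = fus_fs(aln, n_reps=n_reps, seed=seed)
    sel = pn_ps_dn_ds(aln) if aln.coding else None
    return DiversitySummary(
        locus=aln.name, n=aln.n, S=segregating_sites(aln), K=table.k,
        Hd=haplotype_diversity(table) if aln.n >= 2 else 0.0,
        pi_abs=pi_abs, pi_per_site=pi_ps,
        theta_w_abs=th_abs, theta_w_per_site=th_ps,
        tajima_d=d, tajima_p=d_p, fu_fs=fs, fu_p=fs_p, selection=sel,
    )
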