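"""Diversity indexes and site-frequency-spectrum neutrality tests.

All statistics are computed on the analyzed columns (no gap/N in any
ingroup sequence, complete deletion).  Synonymous/nonsynonymous diversity
uses the Nei–Gojobori pathway method with uncorrected p-distances.
Fu & Li's D and F are the outgroup versions; Fay & Wu's H is the
unnormalized per-locus form theta_pi - theta_H.  Significance is assessed
against a fixed-S neutral coalescent null (two-tailed, add-one
smoothing).

Derived states are polarized with the outgroup: sites where the outgroup
carries a gap/N, or a state absent from the ingroup, cannot be polarized
and are skipped (their number is reported).
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .mutmap import _CODON_TO_AA
from .seqio import Alignment, HapsurvError

logger = logging.getLogger("hapsurv")

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


class InsufficientDataError(HapsurvError):
    """Fewer sequences than the statistic requires."""


class MissingOutgroupError(HapsurvError):
    """An outgroup-polarized statistic was requested without an outgroup."""


class DegenerateError(HapsurvError):
    """Degenerate inputs (e.g. both standard deviations zero)."""


# ---------------------------------------------------------------------------
# encoded matrices

def _encoded(aln: Alignment):
    """(ingroup matrix coded 0..3, outgroup codes with -1 = unusable, site_index)."""
    if aln.n < 1:
        raise InsufficientDataError("no ingroup sequences")
    cols = aln.analyzed_columns()
    mat = np.empty((aln.n, len(cols)), dtype=np.int8)
    for i, seq in enumerate(aln.ingroup_seqs):
        mat[i] = [_CODE[seq[c]] for c in cols]
    og = None
    if aln.outgroup_seq is not None:
        og = np.array(
            [_CODE.get(aln.outgroup_seq[c], -1) for c in cols], dtype=np.int8
        )
    return mat, og, cols


def _base_counts(mat: np.ndarray) -> np.ndarray:
    """(4, L) counts of each base per column."""
    return np.stack([(mat == b).sum(axis=0) for b in range(4)])


# ---------------------------------------------------------------------------
# standard constants

def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    return dict(a1=a1, a2=a2, e1=c1 / a1, e2=c2 / (a1**2 + a2))


def _fuli_constants(n: int) -> dict[str, float]:
    a = _harmonic(n)
    b = _harmonic(n, 2)
    c = 1.0 if n == 2 else 2.0 * (n * a - 2.0 * (n - 1.0)) / ((n - 1.0) * (n - 2.0))
    vD = 1.0 + (a**2 / (b + a**2)) * (c - (n + 1.0) / (n - 1.0))
    uD = a - 1.0 - vD
    an1 = a + 1.0 / n  # harmonic number up to n
    vF = (c + 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0)) - 2.0 / (n - 1.0)) / (
        a**2 + b
    )
    uF = (
        1.0
        + (n + 1.0) / (3.0 * (n - 1.0))
        - 4.0 * ((n + 1.0) / (n - 1.0) ** 2) * (an1 - 2.0 * n / (n + 1.0))
    ) / a - vF
    return dict(a=a, b=b, c=c, uD=uD, vD=vD, uF=uF, vF=vF)


# ---------------------------------------------------------------------------
# Nei–Gojobori pathway machinery

@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Synonymous site count of a codon (changes to stops count nonsynonymous)."""
    aa = _CODON_TO_AA[codon]
    s = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _CODON_TO_AA[alt] == aa and _CODON_TO_AA[alt] != "*":
                s += 1
    return s / 3.0


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averages over all mutational pathways; pathways through stop codons
    are discarded unless every pathway is blocked.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_TO_AA[nxt] == "*" and nxt != c2:
                blocked = True
            if _CODON_TO_AA[cur] == _CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    usable = [p for p in paths if not p[2]] or paths
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def _codon_strings(aln: Alignment, cols: np.ndarray):
    """Complete codons fully inside the analyzed columns.

    Returns (list of codon column triples as positions into ``cols``,
    original codon indices).
    """
    pos_of = {int(c): i for i, c in enumerate(cols)}
    triples = []
    indices = []
    for col, (ci, pos, cset) in aln.codon_map().items():
        if pos != 0:
            continue
        if all(c in pos_of for c in cset):
            triples.append(tuple(pos_of[c] for c in cset))
            indices.append(ci)
    return triples, indices


# ---------------------------------------------------------------------------
# diversity

@dataclass(frozen=True)
class DiversityStats:
    n: int
    h: int
    Hd: float
    Hd_sd: float
    S: int
    Sy: int | None
    NSy: int | None
    sg: int
    m3: int
    pi: float
    pi_sd: float
    pi_s: float | None
    pi_s_sd: float | None
    pi_a: float | None
    pi_a_sd: float | None
    theta_w: float
    theta_sd: float
    Ls: float | None
    La: float | None


def _pi_stochastic_sd(pi: float, n: int, L: float) -> float:
    """No-recombination (stochastic + sampling) SD of per-site pi."""
    v = (n + 1.0) / (3.0 * (n - 1.0)) * pi / L + (
        2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi * pi
    return math.sqrt(max(v, 0.0))


def diversity(aln: Alignment) -> DiversityStats:
    """Haplotype and nucleotide diversity, theta_w, and the NG86 partition."""
    if aln.n < 2:
        raise InsufficientDataError("need at least two ingroup sequences")
    mat, _, cols = _encoded(aln)
    n, L = mat.shape
    counts = _base_counts(mat)
    n_states = (counts > 0).sum(axis=0)
    seg = n_states >= 2
    S = int(seg.sum())
    sg = int((n_states == 2).sum())
    m3 = int((n_states > 2).sum())

    # haplotype diversity with Nei's sampling variance
    hap_counts = np.array(
        sorted(Counter("".join(_BASES[b] for b in row) for row in mat).values())
    )
    p = hap_counts / n
    sp2 = float((p**2).sum())
    sp3 = float((p**3).sum())
    Hd = n * (1.0 - sp2) / (n - 1.0)
    v_hd = (2.0 / (n * (n - 1.0))) * (
        2.0 * (n - 2.0) * (sp3 - sp2**2) + sp2 - sp2**2
    )
    Hd_sd = math.sqrt(max(v_hd, 0.0))

    # per-site pi over analyzed columns
    pairs = n * (n - 1) / 2.0
    same = (counts * (counts - 1) / 2.0).sum(axis=0)
    pi_total = float(((pairs - same) / pairs).sum())
    pi = pi_total / L
    pi_sd = _pi_stochastic_sd(pi, n, L)

    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    theta_locus = S / a1
    theta_w = theta_locus / L
    theta_sd = math.sqrt(theta_locus / a1 + a2 * theta_locus**2 / a1**2) / L

    # coding partition
    triples, _ = _codon_strings(aln, cols)
    Sy = NSy = None
    pi_s = pi_a = pi_s_sd = pi_a_sd = Ls = La = None
    if triples:
        seqs = ["".join(_BASES[b] for b in row) for row in mat]
        codon_cols = {c for t in triples for c in t}
        # per-sequence site counts
        syn_per_seq = [
            sum(_syn_sites(seq[t[0]] + seq[t[1]] + seq[t[2]]) for t in triples)
            for seq in seqs
        ]
        Ls = float(np.mean(syn_per_seq))
        La = 3.0 * len(triples) - Ls
        sd_sum = nd_sum = 0.0
        ps_vals = []
        pa_vals = []
        for i in range(n):
            for j in range(i + 1, n):
                sd = nd = 0.0
                for t in triples:
                    ci = seqs[i][t[0]] + seqs[i][t[1]] + seqs[i][t[2]]
                    cj = seqs[j][t[0]] + seqs[j][t[1]] + seqs[j][t[2]]
                    if ci != cj:
                        s_, n_ = _pathway_counts(ci, cj)
                        sd += s_
                        nd += n_
                ls_pair = (syn_per_seq[i] + syn_per_seq[j]) / 2.0
                la_pair = 3.0 * len(triples) - ls_pair
                ps_vals.append(sd / ls_pair if ls_pair > 0 else 0.0)
                pa_vals.append(nd / la_pair if la_pair > 0 else 0.0)
                sd_sum += sd
                nd_sum += nd
        pi_s = float(np.mean(ps_vals))
        pi_a = float(np.mean(pa_vals))
        pi_s_sd = _pi_stochastic_sd(pi_s, n, Ls)
        pi_a_sd = _pi_stochastic_sd(pi_a, n, La)

        # polymorphic-site effect classification
        Sy = NSy = 0
        pos_in_codon = {}
        for t in triples:
            for k, c in enumerate(t):
                pos_in_codon[c] = (t, k)
        for col in np.nonzero(seg)[0]:
            if int(col) not in pos_in_codon:
                continue
            t, k = pos_in_codon[int(col)]
            backgrounds = {seqs[i][t[0]] + seqs[i][t[1]] + seqs[i][t[2]] for i in range(n)}
            states = {seqs[i][col] for i in range(n)}
            nonsyn = False
            for bg in backgrounds:
                for x in states:
                    if x == bg[k]:
                        continue
                    alt = bg[:k] + x + bg[k + 1 :]
                    if _CODON_TO_AA[bg] != _CODON_TO_AA[alt]:
                        nonsyn = True
            if nonsyn:
                NSy += 1
            else:
                Sy += 1

    hap_n = len(hap_counts)
    return DiversityStats(
        n=n, h=hap_n, Hd=Hd, Hd_sd=Hd_sd, S=S, Sy=Sy, NSy=NSy, sg=sg, m3=m3,
        pi=pi, pi_sd=pi_sd, pi_s=pi_s, pi_s_sd=pi_s_sd, pi_a=pi_a, pi_a_sd=pi_a_sd,
        theta_w=theta_w, theta_sd=theta_sd, Ls=Ls, La=La,
    )


# ---------------------------------------------------------------------------
# neutrality statistics

def _pi_and_s(mat: np.ndarray) -> tuple[float, int]:
    n = mat.shape[0]
    counts = _base_counts(mat)
    pairs = n * (n - 1) / 2.0
    same = (counts * (counts - 1) / 2.0).sum(axis=0)
    pi_total = float(((pairs - same) / pairs).sum())
    S = int(((counts > 0).sum(axis=0) >= 2).sum())
    return pi_total, S


def tajima_d(aln: Alignment) -> float:
    """Tajima's D (per locus); NaN when S = 0 or n < 4."""
    mat, _, _ = _encoded(aln)
    n = mat.shape[0]
    pi_total, S = _pi_and_s(mat)
    if S == 0 or n < 4:
        logger.info("Tajima's D undefined (S=%d, n=%d); reporting NA", S, n)
        return float("nan")
    k = _tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return (pi_total - S / k["a1"]) / math.sqrt(var)


def _polarized_spectrum(mat: np.ndarray, og: np.ndarray):
    """Counts of each derived state per polarizable segregating site.

    Returns (list of derived-state counts, eta_total, n_skipped).  A site
    is polarizable when the outgroup base is A/C/G/T and occurs among the
    ingroup states; every non-ancestral state contributes one derived
    class with its carrier count.
    """
    n = mat.shape[0]
    counts = _base_counts(mat)
    present = counts > 0
    seg_cols = np.nonzero(present.sum(axis=0) >= 2)[0]
    derived: list[int] = []
    eta = 0
    skipped = 0
    for col in seg_cols:
        a = og[col]
        if a < 0 or not present[a, col]:
            skipped += 1
            continue
        for b in range(4):
            if b != a and present[b, col]:
                derived.append(int(counts[b, col]))
                eta += 1
    return derived, eta, skipped


def fuli_df(aln: Alignment) -> tuple[float, float]:
    """Fu & Li's D and F (outgroup versions), per locus.

    D contrasts the total number of mutations with derived singletons
    (external-branch mutations); F contrasts mean pairwise differences
    with derived singletons.
    """
    if aln.outgroup_seq is None:
        raise MissingOutgroupError(
            "Fu & Li's D/F require an outgroup (starred variants not provided)"
        )
    mat, og, _ = _encoded(aln)
    n = mat.shape[0]
    if n < 3:
        raise InsufficientDataError("Fu & Li's tests require n >= 3")
    derived, eta, skipped = _polarized_spectrum(mat, og)
    if skipped:
        logger.info("Fu & Li: %d sites unpolarizable, skipped", skipped)
    if eta == 0:
        return float("nan"), float("nan")
    eta_e = sum(1 for c in derived if c == 1)
    k = _fuli_constants(n)
    D = (eta - k["a"] * eta_e) / math.sqrt(k["uD"] * eta + k["vD"] * eta * eta)
    pi_total = sum(2.0 * c * (n - c) / (n * (n - 1.0)) for c in derived)
    F = (pi_total - eta_e) / math.sqrt(k["uF"] * eta + k["vF"] * eta * eta)
    return float(D), float(F)


def faywu_h(aln: Alignment) -> tuple[float, float, float, int]:
    """Fay & Wu's unnormalized H = theta_pi - theta_H (per locus).

    Returns (theta_pi, theta_H, H, n_skipped_sites).  Negative H signals
    an excess of high-frequency derived variants.
    """
    if aln.outgroup_seq is None:
        raise MissingOutgroupError("Fay & Wu's H requires an outgroup")
    mat, og, _ = _encoded(aln)
    n = mat.shape[0]
    derived, _, skipped = _polarized_spectrum(mat, og)
    theta_pi = sum(2.0 * c * (n - c) / (n * (n - 1.0)) for c in derived)
    theta_h = sum(2.0 * c * c / (n * (n - 1.0)) for c in derived)
    return float(theta_pi), float(theta_h), float(theta_pi - theta_h), skipped


def diversity_ztest(est1: float, sd1: float, est2: float, sd2: float) -> tuple[float, float]:
    """Two-sample z-test for a difference between two diversity estimates."""
    if sd1 < 0 or sd2 < 0:
        raise DegenerateError("standard deviations must be nonnegative")
    denom = math.hypot(sd1, sd2)
    if denom == 0.0:
        raise DegenerateError("both standard deviations are zero")
    z = (est1 - est2) / denom
    return float(z), float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# fixed-S simulated null

@dataclass(frozen=True)
class NeutralityResult:
    n: int
    S: int
    tajima_D: float
    fuli_D: float | None
    fuli_F: float | None
    faywu_H: float | None
    theta_pi: float | None
    theta_H: float | None
    unresolved_sites: int = 0
    p_values: dict | None = None


def sfs_statistics(sfs: np.ndarray, n: int) -> dict[str, float]:
    """D, Fu & Li D/F and H from a derived-count spectrum.

    ``sfs[i]`` is the number of sites with derived-allele count ``i``
    (index 0 unused).
    """
    i = np.arange(len(sfs))
    S = int(sfs.sum())
    out = dict(tajima_D=float("nan"), fuli_D=float("nan"), fuli_F=float("nan"),
               faywu_H=0.0)
    if S == 0:
        return out
    pi_total = float((sfs * 2.0 * i * (n - i) / (n * (n - 1.0))).sum())
    theta_h = float((sfs * 2.0 * i * i / (n * (n - 1.0))).sum())
    out["faywu_H"] = pi_total - theta_h
    kt = _tajima_constants(n)
    var = kt["e1"] * S + kt["e2"] * S * (S - 1)
    if var > 0:
        out["tajima_D"] = (pi_total - S / kt["a1"]) / math.sqrt(var)
    kf = _fuli_constants(n)
    eta_e = float(sfs[1]) if len(sfs) > 1 else 0.0
    out["fuli_D"] = (S - kf["a"] * eta_e) / math.sqrt(kf["uD"] * S + kf["vD"] * S * S)
    out["fuli_F"] = (pi_total - eta_e) / math.sqrt(kf["uF"] * S + kf["vF"] * S * S)
    return out


def simulated_null(n: int, S: int, reps: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Fixed-S neutral coalescent null distributions of the four statistics."""
    from .coalsim import neutral_branch_spectrum  # deferred: avoids import cycle

    keys = ("tajima_D", "fuli_D", "fuli_F", "faywu_H")
    sims: dict[str, list[float]] = {k: [] for k in keys}
    for _ in range(reps):
        lengths, leaves = neutral_branch_spectrum(n, rng)
        branch = rng.choice(len(lengths), size=S, p=lengths / lengths.sum())
        sfs = np.bincount(leaves[branch], minlength=n)
        st = sfs_statistics(sfs, n)
        for k in keys:
            sims[k].append(st[k])
    return {k: np.asarray(v) for k, v in sims.items()}


def neutrality_pvalues(
    observed: dict[str, float],
    n: int,
    S: int,
    reps: int = 10_000,
    seed: int | None = None,
) -> dict[str, float]:
    """Two-tailed empirical p-values from the fixed-S neutral null.

    p = (1 + #{|sim| >= |obs|}) / (reps + 1) (add-one smoothing).
    """
    if reps < 100:
        logger.warning("neutrality_pvalues: reps=%d is very small", reps)
    rng = np.random.default_rng(seed)
    null = simulated_null(n, S, reps, rng)
    out = {}
    for key, obs in observed.items():
        sims = null.get(key)
        if sims is None or not np.isfinite(obs):
            out[key] = float("nan")
            continue
        sims = sims[np.isfinite(sims)]
        out[key] = float((1 + (np.abs(sims) >= abs(obs)).sum()) / (len(sims) + 1))
    return out


def neutrality(
    aln: Alignment, reps: int = 0, seed: int | None = None
) -> NeutralityResult:
    """All neutrality statistics for one alignment, optionally with p-values.

    Outgroup-requiring statistics are NA when no outgroup is designated.
    """
    mat, og, _ = _encoded(aln)
    n = mat.shape[0]
    _, S = _pi_and_s(mat)
    D = tajima_d(aln)
    fl_d = fl_f = th_pi = th_h = H = None
    skipped = 0
    if aln.outgroup_seq is not None:
        fl_d, fl_f = fuli_df(aln)
        th_pi, th_h, H, skipped = faywu_h(aln)
    pvals = None
    if reps > 0 and S > 0:
        observed = {"tajima_D": D}
        if H is not None:
            observed.update(fuli_D=fl_d, fuli_F=fl_f, faywu_H=H)
        pvals = neutrality_pvalues(observed, n, S, reps=reps, seed=seed)
    return NeutralityResult(
        n=n, S=S, tajima_D=D, fuli_D=fl_d, fuli_F=fl_f, faywu_H=H,
        theta_pi=th_pi, theta_H=th_h, unresolved_sites=skipped, p_values=pvals,
    )
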