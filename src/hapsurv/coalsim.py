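"""Neutral and post-sweep coalescent simulation of codon alignments.

The generator produces ingroup samples plus an outgroup with full
mutation truth, for calibrating the survival test and the SFS neutrality
tests.  Time is in coalescent units of 2N generations; theta = 4*N*mu*L
is the population mutation rate per locus, so E[S] = theta * sum(1/i).

Neutral mode is the standard Kingman coalescent.  Sweep mode models a
hard selective sweep that completed ``tau`` time units ago: lineages
coalesce neutrally between the present and ``tau``; lineages still
distinct at ``tau`` are forced to coalesce there (a star join), except
that each escapes the sweep independently with probability
``sweep_escape_prob`` (the genealogical shorthand for recombining off the
swept background during the sweep) and instead coalesces neutrally above
``tau``.  Escape lineages are what place derived variants at high
frequency after the sweep — the signature, together with the excess of
rare variants from the recovery phase, that distinguishes hitchhiking
from purifying selection.  ``tau = 0`` with no escape gives a pure star.

Sequences are codon alignments: the ancestral sequence is drawn from
sense codons and mutations avoid creating stop codons on their background
(re-drawn; rate distortion negligible at these scales), keeping
synonymous/nonsynonymous classification biologically sane.  There is no
recombination within the locus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .pipeline import analyze_mutations, survival_from_table
from .seqio import Alignment, HapsurvError

logger = logging.getLogger("hapsurv")

_BASES = "ACGT"
_STOP_CODONS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA


class ConfigError(HapsurvError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated locus.

    Defaults match the calibration conditions used throughout: 50
    sampled sequences of a 720-column coding region with theta = 20 per
    locus (~0.028/site, the per-species scale of the fruitless data), a
    close outgroup at 0.005 expected substitutions per site, and for
    sweep mode a sweep ending 0.1 time units ago with a 10% per-lineage
    escape probability.
    """

    n: int = 50
    L: int = 720
    theta: float = 20.0
    mode: str = "neutral"            # neutral | sweep
    tau: float = 0.1
    sweep_escape_prob: float = 0.1
    outgroup_divergence: float = 0.005
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError("n must be >= 2")
        if self.L < 3 or self.L % 3 != 0:
            raise ConfigError("L must be a positive multiple of 3")
        if self.theta < 0:
            raise ConfigError("theta must be >= 0")
        if self.mode not in ("neutral", "sweep"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.tau < 0:
            raise ConfigError("tau must be >= 0")
        if not 0.0 <= self.sweep_escape_prob <= 1.0:
            raise ConfigError("sweep_escape_prob must lie in [0, 1]")
        if self.outgroup_divergence < 0:
            raise ConfigError("outgroup_divergence must be >= 0")


@dataclass(frozen=True)
class TrueMutation:
    site: int
    node: int              # child node of the branch carrying the mutation
    ancestral: str
    derived: str
    derived_leaves: int
    derived_haplotypes: int


@dataclass(frozen=True)
class SimReplicate:
    config: SimConfig
    parent: np.ndarray     # parent[i] = parent node id, -1 for the root
    node_time: np.ndarray
    alignment: Alignment
    truth: tuple[TrueMutation, ...]
    root_sequence: str = ""

    @property
    def root(self) -> int:
        return int(np.nonzero(self.parent < 0)[0][0])


# ---------------------------------------------------------------------------
# genealogy

def _genealogy(cfg: SimConfig, rng: np.random.Generator):
    """Parent/time arrays; leaves are nodes 0..n-1, parents appended later."""
    parent = [-1] * cfg.n
    time = [0.0] * cfg.n
    active = list(range(cfg.n))
    t = 0.0

    def merge(nodes: list[int], at: float) -> int:
        new = len(parent)
        parent.append(-1)
        time.append(at)
        for x in nodes:
            parent[x] = new
        return new

    def kingman_step() -> None:
        nonlocal t
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        del active[j], active[i]
        active.append(merge([a, b], t))

    if cfg.mode == "sweep":
        # neutral coalescence during the post-sweep recovery (0, tau)
        while len(active) > 1:
            k = len(active)
            dt = rng.exponential(2.0 / (k * (k - 1)))
            if t + dt >= cfg.tau:
                break
            t += dt
            i, j = sorted(rng.choice(k, size=2, replace=False))
            a, b = active[i], active[j]
            del active[j], active[i]
            active.append(merge([a, b], t))
        if len(active) > 1:
            t = cfg.tau
            escaped_mask = rng.random(len(active)) < cfg.sweep_escape_prob
            swept = [a for a, e in zip(active, escaped_mask) if not e]
            escaped = [a for a, e in zip(active, escaped_mask) if e]
            if len(swept) >= 2:
                star = merge(swept, cfg.tau)
                active = escaped + [star]
            # with <2 swept lineages the sweep leaves no mark

    while len(active) > 1:
        kingman_step()

    return np.asarray(parent), np.asarray(time, dtype=float)


def _branch_arrays(parent: np.ndarray, node_time: np.ndarray, n_leaves: int):
    """(node ids with a parent, branch lengths, subtended leaf counts)."""
    n_nodes = len(parent)
    leaves = np.zeros(n_nodes, dtype=int)
    leaves[:n_leaves] = 1
    for i in range(n_nodes):  # children precede parents by construction
        if parent[i] >= 0:
            leaves[parent[i]] += leaves[i]
    nodes = np.nonzero(parent >= 0)[0]
    lengths = node_time[parent[nodes]] - node_time[nodes]
    return nodes, lengths, leaves


def neutral_branch_spectrum(n: int, rng: np.random.Generator):
    """(branch lengths, subtended leaf counts) of one neutral genealogy.

    Fast path for fixed-S null simulation: mutations dropped on branches
    proportionally to length get derived-allele count = leaf count.
    """
    cfg = SimConfig(n=n, L=3, theta=0.0)
    parent, node_time = _genealogy(cfg, rng)
    nodes, lengths, leaves = _branch_arrays(parent, node_time, n)
    return lengths, leaves[nodes]


# ---------------------------------------------------------------------------
# sequences

_SENSE_CODONS = [
    (a, b, c)
    for a in range(4)
    for b in range(4)
    for c in range(4)
    if (a, b, c) not in _STOP_CODONS
]


def _random_root(L: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(0, len(_SENSE_CODONS), size=L // 3)
    return np.array([_SENSE_CODONS[i] for i in idx], dtype=np.int8).reshape(-1)


def _mutate_base(seq: np.ndarray, site: int, rng: np.random.Generator) -> tuple[int, int]:
    """Pick a derived base avoiding stop codons on the current background."""
    cur = int(seq[site])
    c0 = 3 * (site // 3)
    codon = [int(seq[c0]), int(seq[c0 + 1]), int(seq[c0 + 2])]
    pos = site - c0
    options = []
    for b in range(4):
        if b == cur:
            continue
        codon[pos] = b
        if tuple(codon) not in _STOP_CODONS:
            options.append(b)
    codon[pos] = cur
    if not options:  # cannot happen under the standard code; kept as a guard
        options = [b for b in range(4) if b != cur]
    return cur, int(options[rng.integers(0, len(options))])


def simulate(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimReplicate:
    """One replicate: genealogy, codon alignment with outgroup, truth."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    parent, node_time = _genealogy(cfg, rng)
    nodes, lengths, leaves = _branch_arrays(parent, node_time, cfg.n)

    total = float(lengths.sum())
    n_mut = rng.poisson(cfg.theta / 2.0 * total) if total > 0 and cfg.theta > 0 else 0
    if n_mut > cfg.L:
        raise ConfigError(
            f"{n_mut} mutations exceed {cfg.L} sites: theta too large for "
            "the infinite-sites approximation at this locus length"
        )
    sites = rng.choice(cfg.L, size=n_mut, replace=False) if n_mut else np.array([], int)
    if n_mut:
        branch_of = rng.choice(len(nodes), size=n_mut, p=lengths / total)
    mut_by_node: dict[int, list[int]] = {}
    for m in range(n_mut):
        mut_by_node.setdefault(int(nodes[branch_of[m]]), []).append(int(sites[m]))

    # depth-first sequence propagation with undo, recording each mutation
    children: dict[int, list[int]] = {}
    for i in range(len(parent)):
        if parent[i] >= 0:
            children.setdefault(int(parent[i]), []).append(i)
    root = int(np.nonzero(parent < 0)[0][0])
    seq = _random_root(cfg.L, rng)
    root_seq = seq.copy()
    leaf_seqs: dict[int, np.ndarray] = {}
    raw: list[tuple[int, int, int, int]] = []  # (site, node, anc, der)

    stack: list[tuple[int, bool, list[tuple[int, int]]]] = [(root, False, [])]
    while stack:
        node, done, undo = stack.pop()
        if done:
            for site, base in reversed(undo):
                seq[site] = base
            continue
        undo = []
        for site in sorted(mut_by_node.get(node, [])):
            anc, der = _mutate_base(seq, site, rng)
            raw.append((site, node, anc, der))
            undo.append((site, anc))
            seq[site] = der
        if node < cfg.n:
            leaf_seqs[node] = seq.copy()
        stack.append((node, True, undo))
        for ch in sorted(children.get(node, []), reverse=True):
            stack.append((ch, False, []))

    # outgroup from the root, Poisson hits per site (multiple hits allowed)
    og = root_seq.copy()
    hits = rng.poisson(cfg.outgroup_divergence, size=cfg.L)
    for site in np.nonzero(hits)[0]:
        for _ in range(int(hits[site])):
            cur = int(og[site])
            og[site] = (cur + 1 + int(rng.integers(0, 3))) % 4

    ids = tuple(f"s{i + 1:03d}" for i in range(cfg.n)) + ("outgroup",)
    decode = np.array(list(_BASES))
    seq_strings = tuple("".join(decode[leaf_seqs[i]]) for i in range(cfg.n)) + (
        "".join(decode[og]),
    )
    aln = Alignment(
        ids=ids,
        seqs=seq_strings,
        coding_mask=((0, cfg.L, 0),),
        outgroup_id="outgroup",
    )

    hap_key = {i: seq_strings[i] for i in range(cfg.n)}
    leaf_sets: dict[int, set[int]] = {i: {i} for i in range(cfg.n)}
    for i in range(len(parent)):
        if i not in leaf_sets:
            leaf_sets[i] = set()
            stack2 = list(children.get(i, []))
            while stack2:
                x = stack2.pop()
                if x < cfg.n:
                    leaf_sets[i].add(x)
                else:
                    stack2.extend(children.get(x, []))
    truth = tuple(
        TrueMutation(
            site=site,
            node=node,
            ancestral=_BASES[anc],
            derived=_BASES[der],
            derived_leaves=int(leaves[node]),
            derived_haplotypes=len({hap_key[l] for l in leaf_sets[node]}),
        )
        for site, node, anc, der in sorted(raw)
    )
    return SimReplicate(
        config=cfg, parent=parent, node_time=node_time, alignment=aln, truth=truth,
        root_sequence="".join(decode[root_seq]),
    )


def simulate_neutral(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimReplicate:
    if cfg.mode != "neutral":
        raise ConfigError("simulate_neutral requires mode='neutral'")
    return simulate(cfg, rng)


def simulate_sweep(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimReplicate:
    if cfg.mode != "sweep":
        raise ConfigError("simulate_sweep requires mode='sweep'")
    return simulate(cfg, rng)


# ---------------------------------------------------------------------------
# calibration harness

@dataclass(frozen=True)
class CalibrationResult:
    test: str
    alpha: float
    reps: int
    used: int
    excluded: int
    rejections: int
    rate: float
    ci_low: float
    ci_high: float
    config: SimConfig = field(repr=False, default=None)


_SFS_TESTS = {
    "tajima_d": "tajima_D",
    "fuli_d": "fuli_D",
    "fuli_f": "fuli_F",
    "faywu_h": "faywu_H",
}


def calibrate(
    test: str,
    cfg: SimConfig,
    reps: int,
    alpha: float = 0.05,
    seed: int | None = None,
    min_f: int = 3,
    null_reps: int = 200,
    method: str = "normal",
    continuity: bool = False,
) -> CalibrationResult:
    """Rejection rate of a test over simulated replicates.

    ``test`` is ``'survival'`` (the full collapse -> network -> orient ->
    classify -> rank-test pipeline) or one of the SFS statistics
    (``'tajima_d'``, ``'fuli_d'``, ``'fuli_f'``, ``'faywu_h'``), whose
    p-values come from a fixed-S neutral null (cached per observed S).
    Replicates where a test cannot run (an empty effect group, S = 0)
    are excluded and counted.

    For the survival test the harness calibrates the tie-corrected
    normal z without continuity correction: the exact permutation test
    and the continuity-corrected approximation of it are deliberately
    conservative under the heavy ties of descendant-haplotype counts, so
    their rejection rate sits below the nominal level by construction
    and nominal-size calibration is only informative for the plain
    z-statistic.  Pass ``method``/``continuity`` to calibrate the other
    variants.
    """
    from .sfsstats import neutrality  # deferred: import cycle

    if reps < 100:
        logger.warning("calibrate: reps=%d is very small", reps)
    if test != "survival" and test not in _SFS_TESTS:
        raise ValueError(f"unknown test {test!r}")

    ss = np.random.SeedSequence(seed if seed is not None else cfg.seed)
    rep_seeds = ss.spawn(reps + 1)
    null_rng = np.random.default_rng(rep_seeds[-1])
    null_cache: dict[int, dict[str, np.ndarray]] = {}

    rejections = used = excluded = 0
    for r in range(reps):
        rng = np.random.default_rng(rep_seeds[r])
        rep = simulate(cfg, rng)
        aln = rep.alignment
        if test == "survival":
            _, _, table = analyze_mutations(aln)
            res, _ = survival_from_table(
                table, min_f=min_f, method=method, continuity=continuity
            )
            if res is None:
                excluded += 1
                continue
            used += 1
            rejections += res.p_two_tailed <= alpha
        else:
            obs = neutrality(aln, reps=0)
            key = _SFS_TESTS[test]
            value = getattr(obs, key)
            if obs.S == 0 or value is None or not math.isfinite(value):
                excluded += 1
                continue
            if obs.S not in null_cache:
                null_cache[obs.S] = _null_stats(cfg.n, obs.S, null_reps, null_rng)
            sims = null_cache[obs.S][key]
            p = (1 + (np.abs(sims) >= abs(value)).sum()) / (len(sims) + 1)
            used += 1
            rejections += p <= alpha
    rate = rejections / used if used else float("nan")
    half = 1.96 * math.sqrt(rate * (1 - rate) / used) if used else float("nan")
    if excluded:
        logger.info("calibrate(%s): %d/%d replicates excluded", test, excluded, reps)
    return CalibrationResult(
        test=test, alpha=alpha, reps=reps, used=used, excluded=excluded,
        rejections=rejections, rate=rate,
        ci_low=max(0.0, rate - half), ci_high=min(1.0, rate + half),
        config=cfg,
    )


def _null_stats(n: int, S: int, reps: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    from .sfsstats import simulated_null  # deferred: import cycle

    return simulated_null(n, S, reps, rng)


def write_truth(rep: SimReplicate, path) -> None:
    """Export the true mutation list as TSV."""
    with open(path, "w") as fh:
        fh.write("site\tposition\tnode\tancestral\tderived\tderived_leaves\tderived_haplotypes\n")
        for m in rep.truth:
            fh.write(
                f"{m.site}\t{m.site + 1}\t{m.node}\t{m.ancestral}\t{m.derived}"
                f"\t{m.derived_leaves}\t{m.derived_haplotypes}\n"
            )
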