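"""Pairwise Phi_ST between populations from haplotype alignments.

Differentiation is measured by a two-level analysis of molecular variance
(AMOVA) on uncorrected genetic distances: the among-population variance
component sigma2_a over the total molecular variance,

    Phi_ST = sigma2_a / (sigma2_a + sigma2_b).

Distances are raw counts of differing sites with pairwise deletion of gaps
and ambiguous bases (no substitution-model correction).  Significance is
assessed by permuting individuals among populations (sample sizes
preserved), by default 1,023 permutations with the add-one correction so
the p-value is never exactly zero.

sigma2_a can be slightly negative near panmixia; it is reported as computed
(no truncation at zero by default) because downstream regression on Phi_ST
should see the estimator's actual sampling behavior.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeAlignment",
    "PhiStResult",
    "pairwise_distance_matrix",
    "amova_phi_st",
    "phi_st_permutation_test",
    "flag_divergent_haplotypes",
    "pairwise_phi_st_table",
]

_VALID = frozenset(b"ACGT")


@dataclass
class HaplotypeAlignment:
    """Aligned sequences from one population (A/C/G/T/-/N alphabet)."""

    population: str
    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must have equal length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(
                f"population {self.population!r}: sequences differ in length {sorted(lengths)}"
            )

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class PhiStResult:
    """AMOVA output for one comparison."""

    phi_st: float
    sigma2_among: float
    sigma2_within: float
    p_value: float | None = None
    n_permutations: int = 0
    n_samples: dict = field(default_factory=dict)


def _encode(seqs: list[str]) -> np.ndarray:
    """(n, L) uint8 matrix; 255 marks gaps/N/anything non-ACGT."""
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences differ in length: {sorted(lengths)}")
    arr = np.frombuffer("".join(s.upper() for s in seqs).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(seqs), -1).copy()
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[arr]


def pairwise_distance_matrix(seqs: list[str]) -> np.ndarray:
    """Uncorrected pairwise distances: count of differing unambiguous sites.

    Sites where either sequence carries a gap or an ambiguous base are
    dropped for that pair (pairwise deletion).
    """
    enc = _encode(seqs)
    n = enc.shape[0]
    valid = enc != 255
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = (enc[i] != enc[i + 1 :]) & both
        d[i, i + 1 :] = diff.sum(axis=1)
    return d + d.T


def _labels_to_index(labels) -> tuple[np.ndarray, list]:
    labels = list(labels)
    levels = sorted(set(labels), key=labels.index)
    idx = np.array([levels.index(l) for l in labels])
    return idx, levels


def _amova_components(d2: np.ndarray, idx: np.ndarray, n_pops: int) -> tuple[float, float]:
    """Variance components (sigma2_a, sigma2_b) from squared distances.

    SSD(total) = sum_{i<j} d2_ij / N; SSD(within) = sum over populations of
    the same quantity restricted to the population.  Mean squares use the
    unequal-sample-size coefficient n' = (N - sum n_p^2 / N) / (P - 1).
    """
    N = d2.shape[0]
    sizes = np.bincount(idx, minlength=n_pops).astype(float)
    ssd_total = d2.sum() / (2.0 * N)
    ssd_within = 0.0
    for p in range(n_pops):
        mask = idx == p
        ssd_within += d2[np.ix_(mask, mask)].sum() / (2.0 * sizes[p])
    ssd_among = ssd_total - ssd_within
    df_among = n_pops - 1
    df_within = N - n_pops
    ms_among = ssd_among / df_among
    ms_within = ssd_within / df_within
    n_prime = (N - np.sum(sizes**2) / N) / df_among
    sigma2_b = ms_within
    sigma2_a = (ms_among - ms_within) / n_prime
    return float(sigma2_a), float(sigma2_b)


def amova_phi_st(distmat: np.ndarray, population_labels) -> PhiStResult:
    """Two-level AMOVA on a distance matrix with population labels.

    Requires >= 2 populations with >= 2 members each.  Raises if there is
    no molecular variance at all (Phi_ST undefined).
    """
    d = np.asarray(distmat, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    idx, levels = _labels_to_index(population_labels)
    if len(levels) < 2:
        raise ValueError("need >= 2 populations")
    sizes = np.bincount(idx)
    if sizes.min() < 2:
        raise ValueError("each population needs >= 2 members")
    if d.shape[0] != idx.shape[0]:
        raise ValueError("labels length must match distance matrix")
    if d.sum() == 0.0:
        raise ValueError("Phi_ST undefined (no molecular variance)")
    sigma2_a, sigma2_b = _amova_components(d**2, idx, len(levels))
    denom = sigma2_a + sigma2_b
    if denom == 0.0:
        raise ValueError("Phi_ST undefined (no molecular variance)")
    return PhiStResult(
        phi_st=sigma2_a / denom,
        sigma2_among=sigma2_a,
        sigma2_within=sigma2_b,
        n_samples={lev: int(s) for lev, s in zip(levels, sizes)},
    )


def phi_st_permutation_test(
    distmat: np.ndarray,
    labels,
    n_perm: int = 1023,
    seed: int | None = 0,
) -> PhiStResult:
    """Permutation test: shuffle individuals among populations.

    p = (#{permuted Phi_ST >= observed} + 1) / (n_perm + 1), so p > 0
    always.  Deterministic given the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    result = amova_phi_st(distmat, labels)
    d2 = np.asarray(distmat, dtype=float) ** 2
    idx, levels = _labels_to_index(labels)
    rng = np.random.default_rng(seed)
    n_pops = len(levels)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        sa, sb = _amova_components(d2, perm, n_pops)
        denom = sa + sb
        phi = sa / denom if denom != 0.0 else -np.inf
        if phi >= result.phi_st - 1e-12:
            count += 1
    result.p_value = (count + 1) / (n_perm + 1)
    result.n_permutations = n_perm
    return result


def flag_divergent_haplotypes(
    alignment: HaplotypeAlignment,
    threshold: float | None = None,
) -> tuple[HaplotypeAlignment, HaplotypeAlignment]:
    """Partition an alignment into (kept, excluded) putative introgressants.

    A sequence is excluded when its minimum uncorrected distance to any
    other sequence exceeds ``threshold`` (default: 5x the median nonzero
    pairwise distance).  This catches minority outliers far from the main
    haplotype cloud; two balanced divergent clusters trip a logged warning
    but exclude nothing, since neither is a minority outlier.  Exclusions
    are always logged.
    """
    if len(alignment) < 3:
        raise ValueError("need >= 3 sequences to flag outliers")
    d = pairwise_distance_matrix(alignment.sequences)
    nonzero = d[np.triu_indices_from(d, k=1)]
    nonzero = nonzero[nonzero > 0]
    if threshold is None:
        if nonzero.size == 0:
            threshold = np.inf  # monomorphic: nothing can be an outlier
        else:
            threshold = 5.0 * float(np.median(nonzero))
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    off = d + np.diag(np.full(len(alignment), np.inf))
    min_dist = off.min(axis=1)
    flagged = min_dist > threshold

    if not flagged.any() and np.isfinite(threshold) and nonzero.size:
        # structure check: does the nearest-neighbor graph split into
        # divergent clusters?  (the median pairwise distance would be
        # inflated by the clusters themselves, so use the nearest-neighbor
        # scale here)
        nn_nonzero = min_dist[min_dist > 0]
        conn_thr = 5.0 * float(np.median(nn_nonzero)) if nn_nonzero.size else threshold
        adj = off <= conn_thr
        n = adj.shape[0]
        seen = np.zeros(n, bool)
        stack = [0]
        seen[0] = True
        while stack:
            i = stack.pop()
            for j in np.nonzero(adj[i] & ~seen)[0]:
                seen[j] = True
                stack.append(int(j))
        if not seen.all():
            logger.warning(
                "population %s: divergent haplotype clusters present but no "
                "minority outlier; nothing excluded",
                alignment.population,
            )

    keep = [i for i in range(len(alignment)) if not flagged[i]]
    drop = [i for i in range(len(alignment)) if flagged[i]]
    for i in drop:
        logger.info(
            "population %s: excluding divergent haplotype %s "
            "(min distance %.1f > threshold %.1f)",
            alignment.population, alignment.ids[i], min_dist[i], threshold,
        )
    kept = HaplotypeAlignment(
        population=alignment.population,
        ids=[alignment.ids[i] for i in keep],
        sequences=[alignment.sequences[i] for i in keep],
    )
    excluded = HaplotypeAlignment(
        population=alignment.population,
        ids=[alignment.ids[i] for i in drop],
        sequences=[alignment.sequences[i] for i in drop],
    )
    return kept, excluded


def pairwise_phi_st_table(
    alignments: dict[str, HaplotypeAlignment],
    n_perm: int = 1023,
    seed: int | None = 0,
    exclude_divergent: bool = False,
) -> pd.DataFrame:
    """Phi_ST and permutation p for every unordered population pair.

    Returns a long-format table (pop1, pop2, phi_st, p_value, n1, n2,
    error); per-pair AMOVA failures are recorded in the error column and
    the remaining pairs proceed.
    """
    pops = list(alignments)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    if exclude_divergent:
        cleaned = {}
        for pop, aln in alignments.items():
            kept, dropped = flag_divergent_haplotypes(aln)
            if len(dropped):
                logger.info(
                    "population %s: %d divergent haplotype(s) excluded from "
                    "Phi_ST", pop, len(dropped),
                )
            cleaned[pop] = kept
        alignments = cleaned
    rows = []
    rng = np.random.default_rng(seed)
    for pop1, pop2 in itertools.combinations(pops, 2):
        a1, a2 = alignments[pop1], alignments[pop2]
        seqs = list(a1.sequences) + list(a2.sequences)
        labels = [pop1] * len(a1) + [pop2] * len(a2)
        row = {"pop1": pop1, "pop2": pop2, "n1": len(a1), "n2": len(a2)}
        try:
            d = pairwise_distance_matrix(seqs)
            res = phi_st_permutation_test(
                d, labels, n_perm=n_perm, seed=int(rng.integers(0, 2**31))
            )
            row.update(phi_st=res.phi_st, p_value=res.p_value, error="")
        except ValueError as exc:
            row.update(phi_st=np.nan, p_value=np.nan, error=str(exc))
            logger.warning("pair (%s, %s): %s", pop1, pop2, exc)
        rows.append(row)
    return pd.DataFrame(rows)
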