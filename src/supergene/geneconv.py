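"""Detection of putative gene-conversion / recombination tracts between
supergene haplotype classes within a species.

The scan works in the spirit of Sawyer's inner-fragment statistic: for each
pair of haplotypes drawn from different allele classes, only columns that
are polymorphic in the full alignment are considered; matching columns score
+1 and mismatching columns score ``-mismatch_penalty``, and the
maximal-scoring contiguous segment (found by a linear max-subarray scan) is
the candidate conversion tract.  Significance comes from permuting column
order: the raw p-value is the fraction of permutations whose global maximum
score reaches the observed one, Bonferroni-corrected across the haplotype
pairs tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConversionTract:
    """A candidate conversion/recombination tract between two haplotypes.

    ``start_col``/``end_col`` index the polymorphic-column space (inclusive);
    ``start_pos``/``end_pos`` are the corresponding reference coordinates.
    """

    hap_a: str
    hap_b: str
    class_a: str
    class_b: str
    start_col: int
    end_col: int
    start_pos: int
    end_pos: int
    score: float
    n_match: int
    n_mismatch: int
    p_raw: float
    p_corrected: float


def max_scoring_segment(x: np.ndarray) -> tuple[float, int, int]:
    """Maximal-sum contiguous segment (Kadane); returns (score, start, end)
    with inclusive ends, preferring the leftmost-then-shortest maximum."""
    best = -math.inf
    best_span = (0, -1)
    cur = 0.0
    cur_start = 0
    for i, v in enumerate(x):
        if cur <= 0:
            cur = float(v)
            cur_start = i
        else:
            cur += float(v)
        if cur > best:
            best = cur
            best_span = (cur_start, i)
    return best, best_span[0], best_span[1]


def _max_scores_batch(mat: np.ndarray) -> np.ndarray:
    """Row-wise maximal-subarray scores via prefix sums (vectorised Kadane)."""
    prefix = np.cumsum(mat, axis=1)
    prefix = np.concatenate([np.zeros((mat.shape[0], 1)), prefix], axis=1)
    running_min = np.minimum.accumulate(prefix[:, :-1], axis=1)
    return (prefix[:, 1:] - running_min).max(axis=1)


def silent_site_mask(
    positions: np.ndarray, exon_intervals: list[tuple[int, int]] | None = None
) -> np.ndarray:
    """Boolean mask of columns outside annotated exon intervals (1-based
    inclusive); identity when no annotation is given.  A proxy for
    restricting the scan to silent sites on a mostly non-coding region."""
    mask = np.ones(len(positions), dtype=bool)
    if exon_intervals:
        for s, e in exon_intervals:
            mask &= ~((positions >= s) & (positions <= e))
    return mask


def detect_tracts(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    class_labels,
    hap_ids=None,
    mismatch_penalty: float | None = None,
    n_permutations: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    exon_intervals: list[tuple[int, int]] | None = None,
) -> list[ConversionTract]:
    """Scan all between-class haplotype pairs for significant shared tracts.

    Parameters
    ----------
    haplotypes:
        ``(n_haplotypes, n_sites)`` 0/1 array of phased alleles.
    positions:
        1-based reference coordinate per column.
    class_labels:
        Allele-class label per haplotype; only pairs with different labels
        are compared.
    mismatch_penalty:
        Per-pair score penalty for mismatching columns; defaults to
        ``m/(1-m)`` where ``m`` is the pair's mismatch fraction, so that the
        expected score of a random column is zero.
    Returns tracts with Bonferroni-corrected p < ``alpha``.  Pairs with
    fewer than two polymorphic columns are skipped (identical or
    near-identical sequences carry no signal for this test).
    """
    H = np.asarray(haplotypes, dtype=np.int8)
    positions = np.asarray(positions)
    labels = np.asarray(class_labels)
    if hap_ids is None:
        hap_ids = [f"hap{i}" for i in range(H.shape[0])]
    if len(set(labels)) < 2:
        raise ValueError("need >= 2 haplotype classes")

    keep = silent_site_mask(positions, exon_intervals)
    # polymorphic columns of the full alignment
    poly = keep & (H.min(axis=0) != H.max(axis=0))
    cols = np.nonzero(poly)[0]
    if cols.size < 2:
        return []
    Hp = H[:, cols]
    pos_p = positions[cols]

    pairs = [
        (i, j)
        for i in range(H.shape[0])
        for j in range(i + 1, H.shape[0])
        if labels[i] != labels[j]
    ]
    n_tests = len(pairs)
    rng = np.random.default_rng(seed)
    out: list[ConversionTract] = []
    for i, j in pairs:
        match = (Hp[i] == Hp[j]).astype(float)
        m = 1.0 - match.mean()
        if m == 0.0 or m == 1.0:
            continue  # identical / fully mismatching: no inner fragment test
        penalty = mismatch_penalty if mismatch_penalty is not None else m / (1 - m)
        x = np.where(match == 1, 1.0, -penalty)
        score, c0, c1 = max_scoring_segment(x)
        if score <= 0:
            continue
        perm = np.tile(x, (n_permutations, 1))
        rng.permuted(perm, axis=1, out=perm)
        perm_max = _max_scores_batch(perm)
        p_raw = float((1 + np.sum(perm_max >= score - 1e-12)) / (n_permutations + 1))
        p_corr = min(1.0, p_raw * n_tests)
        if p_corr < alpha:
            seg = x[c0 : c1 + 1]
            out.append(
                ConversionTract(
                    hap_a=str(hap_ids[i]),
                    hap_b=str(hap_ids[j]),
                    class_a=str(labels[i]),
                    class_b=str(labels[j]),
                    start_col=int(cols[c0]),
                    end_col=int(cols[c1]),
                    start_pos=int(pos_p[c0]),
                    end_pos=int(pos_p[c1]),
                    score=float(score),
                    n_match=int(np.sum(seg > 0)),
                    n_mismatch=int(np.sum(seg < 0)),
                    p_raw=p_raw,
                    p_corrected=p_corr,
                )
            )
    return out


def tracts_to_frame(tracts: list[ConversionTract]):
    """TSV-ready table mirroring a supplementary-table layout."""
    import dataclasses

    import pandas as pd

    return pd.DataFrame(
        [dataclasses.asdict(t) for t in tracts],
        columns=[f.name for f in dataclasses.fields(ConversionTract)],
    )
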