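"""Image-fidelity metrics and paired model-comparison statistics.

PSNR here is computed over a brain mask: MSE restricted to masked voxels
and the peak R taken as the masked maximum of the reference image.
Whole-volume PSNR on brain images is dominated by background zeros, so
the masked convention changes absolute dB values — comparisons should
always use one convention throughout.

Method comparison uses the two-sided Wilcoxon signed-rank test on
per-case paired differences (exact distribution for n <= 25, normal
approximation with continuity correction above), Bonferroni-adjusted by
the number of method pairs, plus Cohen's d computed as mean(diff) /
SD(diff) (the paired-data variant).
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np
from scipy import stats

from .volume import Mask, Volume

__all__ = [
    "EvalReport",
    "psnr",
    "intensity_profile",
    "percentile_cases",
    "compare_methods",
]


@dataclasses.dataclass
class EvalReport:
    """Per-case PSNRs per method, medians, and pairwise statistics."""

    per_case: dict                  # method -> list of (case id, PSNR dB)
    medians: dict                   # method -> median PSNR
    pairwise: list                  # dicts per method pair

    def to_frames(self):
        """(per-case DataFrame, pairwise DataFrame) for CSV export."""
        import pandas as pd

        rows = [
            {"method": m, "case": cid, "psnr_db": v}
            for m, cases in self.per_case.items() for cid, v in cases
        ]
        return pd.DataFrame(rows), pd.DataFrame(self.pairwise)

    def summary(self) -> dict:
        return {"medians": dict(self.medians), "pairwise": list(self.pairwise)}


def _arr(x):
    return np.asarray(x.data if isinstance(x, Volume) else x, dtype=float)


def _mask(m):
    return (m.data if isinstance(m, Mask) else np.asarray(m)).astype(bool)


def psnr(x, ref, mask) -> float:
    """Masked peak signal-to-noise ratio, 10*log10(R^2 / MSE) in dB.

    R is the masked maximum of the reference; identical inputs return
    ``inf`` as a sentinel.
    """
    xa, ra, m = _arr(x), _arr(ref), _mask(mask)
    if xa.shape != ra.shape or xa.shape != m.shape:
        raise ValueError("psnr inputs must share one shape")
    if not m.any():
        raise ValueError("empty mask")
    peak = float(np.max(ra[m]))
    if peak <= 0:
        raise ValueError("degenerate reference: masked maximum is not positive")
    mse = float(np.mean((xa[m] - ra[m]) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(peak ** 2 / mse))


def intensity_profile(vol, axis: int, slice_index: int, line_index: int):
    """Voxel values along one in-slice line, in index order.

    ``axis`` selects the slicing axis; within the slice the profile runs
    along the higher-numbered remaining axis, indexed by ``line_index``
    on the lower-numbered one.
    """
    data = _arr(vol)
    if axis not in (0, 1, 2):
        raise IndexError(f"axis must be 0, 1 or 2, got {axis}")
    rest = [i for i in range(3) if i != axis]
    if not (0 <= slice_index < data.shape[axis]):
        raise IndexError(f"slice index {slice_index} out of range")
    if not (0 <= line_index < data.shape[rest[0]]):
        raise IndexError(f"line index {line_index} out of range")
    sl = np.moveaxis(data, axis, 0)[slice_index]
    return np.asarray(sl[line_index], dtype=float)


def percentile_cases(scores, percentiles=(90, 50, 10)) -> dict:
    """Case ids nearest the requested score percentiles.

    Percentiles use linear interpolation over the score distribution;
    the case whose value lies nearest is returned, ties broken toward
    the smaller id.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("empty score list")
    ids = [s[0] for s in scores]
    vals = np.array([float(s[1]) for s in scores])
    out = {}
    for p in percentiles:
        target = np.percentile(vals, p)
        dist = np.abs(vals - target)
        best = min(range(len(ids)), key=lambda i: (dist[i], ids[i]))
        out[p] = ids[best]
    return out


def _cohens_d(diff: np.ndarray) -> float:
    sd = float(np.std(diff, ddof=1))
    mean = float(np.mean(diff))
    if sd == 0:
        if mean == 0:
            return 0.0
        return float(np.sign(mean)) * float("inf")
    return mean / sd


def _wilcoxon_p(diff: np.ndarray) -> float:
    """Two-sided signed-rank p; exact for n <= 25 after dropping zeros.

    The exact branch convolves the signed-rank distribution over doubled
    midranks, which equals brute-force enumeration of all 2^n sign
    patterns and, unlike textbook tables, stays correct under tied
    magnitudes.  Larger n uses the normal approximation with continuity
    correction.
    """
    nz = diff[diff != 0]
    n = nz.size
    if n == 0:
        return 1.0
    if n > 25:
        res = stats.wilcoxon(nz, alternative="two-sided", method="approx",
                             correction=True)
        return float(res.pvalue)
    ranks = stats.rankdata(np.abs(nz))
    r2 = np.round(ranks * 2).astype(int)  # doubled midranks are integers
    total = int(r2.sum())
    dp = np.zeros(total + 1)
    dp[0] = 1.0
    for r in r2:
        new = dp.copy()
        new[r:] += dp[: total + 1 - r]
        dp = new
    dp /= 2.0 ** n
    w = int(r2[nz > 0].sum())
    cdf = float(dp[: w + 1].sum())
    sf = float(dp[w:].sum())
    return float(min(1.0, 2.0 * min(cdf, sf)))


def compare_methods(paired: dict) -> EvalReport:
    """Pairwise comparison of per-case PSNRs across methods.

    ``paired`` maps method name -> list of (case id, value); all methods
    must cover the same case ids.  Fewer than 6 shared cases makes the
    signed-rank test uninformative and raises.
    """
    if len(paired) < 2:
        raise ValueError("need at least 2 methods to compare")
    methods = list(paired)
    case_sets = {m: [c for c, _ in paired[m]] for m in methods}
    ref_cases = case_sets[methods[0]]
    for m in methods[1:]:
        if case_sets[m] != ref_cases:
            raise ValueError(
                f"case ids of {m!r} are not aligned with {methods[0]!r}")
    if len(ref_cases) < 6:
        raise ValueError("need >= 6 shared cases for a meaningful test")

    values = {m: np.array([float(v) for _, v in paired[m]]) for m in methods}
    medians = {m: float(np.median(values[m])) for m in methods}
    pairs = list(combinations(methods, 2))
    pairwise = []
    for m1, m2 in pairs:
        diff = values[m1] - values[m2]
        p = _wilcoxon_p(diff)
        pairwise.append({
            "method_a": m1,
            "method_b": m2,
            "wilcoxon_p": p,
            "bonferroni_p": min(1.0, p * len(pairs)),
            "cohens_d": _cohens_d(diff),
        })
    per_case = {m: [(c, float(v)) for (c, _), v in zip(paired[m], values[m])]
                for m in methods}
    return EvalReport(per_case=per_case, medians=medians, pairwise=pairwise)
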