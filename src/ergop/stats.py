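"""Group statistics: scalar feature tests and the time-frequency cluster test.

Scalar a-/b-wave features are screened for normality with Shapiro–Wilk and
compared between groups with the Wilcoxon rank-sum (Mann–Whitney) test, the
conventional choice for clinical ERG cohorts of unequal size.

The time-frequency comparison thresholds a pointwise Welch two-sample t map
(one-tailed, control > patient by default) at p < alpha, groups significant
points into 4-connected clusters, and scores each cluster by its summed t
(cluster mass).  The null distribution is the maximum cluster mass under
random relabelings of the subjects' group membership, which controls the
familywise error over the whole plane.  Permutation p-values use the
add-one rule p = (1 + #{null >= observed}) / (1 + n_permutations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats as sps

from .errors import DegenerateDataError, ParameterError

FEATURE_COLUMNS = ("a_amp_uV", "a_time_ms", "b_amp_uV", "b_time_ms")


@dataclass
class FeatureTestResult:
    feature: str
    shapiro_p: dict[str, float]
    test_name: str
    statistic: float
    p_value: float
    group_stats: dict[str, tuple[float, float, int]]  # group -> (mean, sd, n)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum via Mann–Whitney U (exact for small, tie-free
    samples; normal approximation with tie correction otherwise)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(np.concatenate([x, y])) == 0:
        raise DegenerateDataError("all observations identical; rank-sum test undefined")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def compare_wave_features(control: pd.DataFrame, achm: pd.DataFrame,
                          features=FEATURE_COLUMNS) -> list[FeatureTestResult]:
    """Shapiro–Wilk per group, then rank-sum control vs patient, per feature."""
    if len(control) < 3 or len(achm) < 3:
        raise ParameterError("need at least 3 subjects per group")
    out = []
    for feat in features:
        x = control[feat].to_numpy(float)
        y = achm[feat].to_numpy(float)
        shapiro = {"control": float(sps.shapiro(x).pvalue),
                   "achm": float(sps.shapiro(y).pvalue)}
        stat, p = rank_sum_test(x, y)
        out.append(FeatureTestResult(
            feature=feat, shapiro_p=shapiro, test_name="wilcoxon_rank_sum",
            statistic=stat, p_value=p,
            group_stats={"control": (float(x.mean()), float(x.std(ddof=1)), x.size),
                         "achm": (float(y.mean()), float(y.std(ddof=1)), y.size)}))
    return out


# ---------------------------------------------------------------------------
# pointwise Welch t maps

def _welch_from_sums(s1, q1, n1, s2, q2, n2):
    """Welch t and degrees of freedom from per-group sums and sums of squares."""
    m1, m2 = s1 / n1, s2 / n2
    v1 = np.maximum(q1 - n1 * m1**2, 0.0) / (n1 - 1)
    v2 = np.maximum(q2 - n2 * m2**2, 0.0) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    t = np.where(se2 > 0, t, 0.0)
    df = np.where(se2 > 0, df, 1.0)
    return t, df


def _tail_p(t, df, tail):
    sf = lambda tt: special.stdtr(df, -tt)  # P(T >= tt)
    if tail == "pos":
        return sf(t)
    if tail == "neg":
        return sf(-t)
    if tail == "two":
        return 2.0 * sf(np.abs(t))
    raise ParameterError(f"unknown tail {tail!r}; expected 'pos', 'neg' or 'two'")


def pointwise_tmap(maps_control: np.ndarray, maps_achm: np.ndarray,
                   alpha: float = 0.05, tail: str = "pos",
                   valid_mask: np.ndarray | None = None):
    """Welch two-sample t at every valid point; mask of p < alpha points.

    Returns (t_map, threshold_mask); invalid points carry t = 0 and False.
    """
    a = np.asarray(maps_control, float)
    b = np.asarray(maps_achm, float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ParameterError("need at least 2 subjects per group")
    if a.shape[1:] != b.shape[1:]:
        raise ParameterError("map shapes differ between groups")
    t, df = _welch_from_sums(a.sum(0), (a**2).sum(0), a.shape[0],
                             b.sum(0), (b**2).sum(0), b.shape[0])
    p = _tail_p(t, df, tail)
    mask = p < alpha
    if valid_mask is not None:
        mask &= valid_mask
        t = np.where(valid_mask, t, 0.0)
    return t, mask


# ---------------------------------------------------------------------------
# clusters

@dataclass
class Cluster:
    indices: np.ndarray           # (n_points, ndim) member coordinates
    mass: float                   # sum of member t-values
    p_value: float | None = None


@dataclass
class ClusterResult:
    t_map: np.ndarray
    threshold_mask: np.ndarray
    clusters: list[Cluster]
    null_max_mass: np.ndarray
    n_permutations: int
    alpha: float
    tail: str
    seed: int


_ADJ_4 = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def find_clusters(mask: np.ndarray, t_map: np.ndarray) -> list[Cluster]:
    """Maximal 4-connected components of the mask, sorted by descending mass."""
    labels, n = ndimage.label(mask, structure=_ADJ_4)
    clusters = []
    for lab in range(1, n + 1):
        sel = labels == lab
        clusters.append(Cluster(indices=np.argwhere(sel),
                                mass=float(t_map[sel].sum())))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def _max_cluster_mass(mask: np.ndarray, t_map: np.ndarray) -> float:
    labels, n = ndimage.label(mask, structure=_ADJ_4)
    if n == 0:
        return 0.0
    masses = ndimage.sum_labels(t_map, labels, index=np.arange(1, n + 1))
    return float(np.max(np.abs(masses)))


def cluster_permutation_test(maps_control: np.ndarray, maps_achm: np.ndarray,
                             n_permutations: int = 1000, alpha: float = 0.05,
                             tail: str = "pos", seed: int = 0,
                             valid_mask: np.ndarray | None = None) -> ClusterResult:
    """Max-cluster-mass permutation test over the time-frequency plane."""
    if n_permutations < 100:
        raise ParameterError("n_permutations must be at least 100")
    a = np.asarray(maps_control, float)
    b = np.asarray(maps_achm, float)
    n1, n2 = a.shape[0], b.shape[0]
    shape = a.shape[1:]
    if valid_mask is None:
        valid_mask = np.ones(shape, dtype=bool)
    cols = valid_mask.ravel()
    X = np.concatenate([a.reshape(n1, -1), b.reshape(n2, -1)])[:, cols]
    X2 = X**2

    def t_and_mask(group1: np.ndarray):
        g = group1.astype(float)
        h = 1.0 - g
        t, df = _welch_from_sums(g @ X, g @ X2, n1, h @ X, h @ X2, n2)
        p = _tail_p(t, df, tail)
        t_full = np.zeros(shape)
        m_full = np.zeros(shape, dtype=bool)
        t_full.ravel()[cols] = t
        m_full.ravel()[cols] = p < alpha
        return t_full, m_full

    observed = np.zeros(n1 + n2)
    observed[:n1] = 1.0
    t_map, mask = t_and_mask(observed)
    clusters = find_clusters(mask, t_map)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        t_p, m_p = t_and_mask(rng.permutation(observed))
        null[i] = _max_cluster_mass(m_p, t_p)
    for c in clusters:
        c.p_value = float((1 + np.sum(null >= abs(c.mass))) / (1 + n_permutations))
    return ClusterResult(t_map, mask, clusters, null, n_permutations, alpha, tail, seed)


def cluster_extent(cluster: Cluster, time_ms: np.ndarray, freqs_hz: np.ndarray) -> dict:
    """Time/frequency bounding box of a cluster, in axis units."""
    ti = cluster.indices[:, 0]
    fi = cluster.indices[:, 1]
    return {"t_min_ms": float(time_ms[ti.min()]), "t_max_ms": float(time_ms[ti.max()]),
            "f_min_hz": float(freqs_hz[fi.min()]), "f_max_hz": float(freqs_hz[fi.max()]),
            "n_points": int(len(cluster.indices))}


def mass_fraction(cluster: Cluster, t_map: np.ndarray, time_ms: np.ndarray,
                  freqs_hz: np.ndarray, t_max_ms: float = 60.0,
                  f_min_hz: float = 100.0) -> float:
    """Fraction of a cluster's mass at frequencies above f_min and times below t_max."""
    ti = cluster.indices[:, 0]
    fi = cluster.indices[:, 1]
    vals = t_map[ti, fi]
    in_region = (freqs_hz[fi] > f_min_hz) & (time_ms[ti] < t_max_ms)
    total = vals.sum()
    return float(vals[in_region].sum() / total) if total != 0 else 0.0
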