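"""Nonparametric inference for frequency-tagging experiments.

Four procedures:

* a Wilcoxon signed-rank test (the per-sensor clustering statistic),
* a sensor-level cluster-based permutation test that controls the
  family-wise error over the sensor array by comparing observed cluster
  masses against the permutation distribution of the maximum cluster mass
  under random participant-wise condition-label flips,
* a participant-level permutation criterion: a participant shows a tagging
  response if their mean stimulation-interval coherence over a selected
  sensor set strictly exceeds 95 % of coherences recomputed after shuffling
  baseline/stimulation trial labels, and
* small summaries: the lateralization index (L - R)/(L + R), ordinary
  least-squares condition slopes, and the percentage of significant
  participants.

Conventions.  The signed-rank statistic is expressed as a z value
``T / sqrt(sum r_i^2)`` with ``T = sum sign(d_i) * rank|d_i|``; zero
differences are discarded and ties get mid-ranks, which makes the variance
``sum r_i^2`` exact under the sign-flip null even with ties.  Cluster mass
is the sum of signed z over an adjacency-connected set of supra-threshold
sensors (a mass statistic rather than cluster size; both observed and
permuted datasets use the same statistic, so the permutation p-value is
valid either way).  Monte-Carlo p-values use the add-one convention
(1 + #null >= obs) / (1 + n_perm) so p is never zero; full sign-flip
enumeration replaces sampling when feasible and requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
import warnings

import numpy as np
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .spectral import TrialCoefficients, coherence_from_coeffs, freq_index

__all__ = [
    "DegenerateTestError",
    "WilcoxonResult",
    "Cluster",
    "ClusterTestResult",
    "ParticipantPermResult",
    "LateralizationResult",
    "wilcoxon_signed_rank",
    "cluster_permutation_test",
    "participant_permutation_test",
    "lateralization_index",
    "fit_condition_slope",
    "proportion_significant",
]


class DegenerateTestError(ValueError):
    """Raised when a test statistic is undefined (e.g. all differences zero)."""


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float        # W+ (sum of positive-difference ranks)
    z_value: float          # signed standardized statistic
    p_value: float
    n_used: int             # pairs remaining after dropping zero differences
    method: str             # 'exact' or 'approx'


def _signed_rank_T(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column T = sum(sign * rank|d|) and its null SD sqrt(sum r^2).

    ``diffs`` is participants x sensors.  Zero differences get rank 0 and
    so drop out of both T and the variance; mid-ranks handle ties.
    """
    absd = np.abs(diffs)
    ranks = sps.rankdata(absd, axis=0)
    # re-rank with zeros excluded: subtract the count of zeros in each column
    nz = absd > 0
    n_zero = (~nz).sum(axis=0)
    ranks = np.where(nz, ranks - n_zero, 0.0)
    T = np.sum(np.sign(diffs) * ranks, axis=0)
    sd = np.sqrt(np.sum(ranks**2, axis=0))
    return T, sd


def wilcoxon_signed_rank(paired_a, paired_b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    The p-value is exact (full enumeration via the scipy implementation)
    for n <= 25 without ties, and a normal approximation otherwise.  The
    z value carries the sign of the paired difference (positive when a
    tends to exceed b); swapping the inputs negates it exactly.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1D arrays of equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateTestError("all paired differences are zero; no test possible")
    if n < 5:
        raise DegenerateTestError(f"only {n} nonzero differences; need at least 5")

    has_ties = np.unique(np.abs(d)).size < n
    method = "approx" if (has_ties or n > 25) else "exact"
    res = sps.wilcoxon(d, alternative="two-sided", method=method, correction=False)
    T, sd = _signed_rank_T(d[:, None])
    z = float(T[0] / sd[0])
    return WilcoxonResult(statistic=float(res.statistic), z_value=z,
                          p_value=float(res.pvalue), n_used=n, method=method)


# ---------------------------------------------------------------------------
# Cluster-based permutation test


@dataclass(frozen=True)
class Cluster:
    sensors: tuple[int, ...]      # indices into the sensor axis
    mass: float                   # signed sum of z over the cluster
    p_value: float


@dataclass(frozen=True)
class ClusterTestResult:
    clusters: list[Cluster]
    z_values: np.ndarray = field(repr=False)
    n_permutations: int = 0
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    tail: str = "two-sided"
    enumerated: bool = False

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.alpha]


def _clusters_from_z(z: np.ndarray, z_crit: float, indptr_adj: csr_matrix
                     ) -> list[tuple[np.ndarray, float]]:
    """Split supra-threshold sensors into adjacency-connected signed clusters."""
    out = []
    for sign in (1.0, -1.0):
        mask = sign * z > z_crit
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        sub = indptr_adj[np.ix_(idx, idx)]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = idx[labels == c]
            out.append((members, float(z[members].sum())))
    return out


def _sign_matrix(n_part: int, n_perm: int, rng: np.random.Generator,
                 enumerate_when_possible: bool) -> tuple[np.ndarray, bool]:
    if enumerate_when_possible and n_perm >= 2**n_part and n_part <= 16:
        signs = np.array(list(product((1.0, -1.0), repeat=n_part)))
        return signs, True
    return rng.choice([1.0, -1.0], size=(n_perm, n_part)), False


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> ClusterTestResult:
    """Paired, two-sided cluster permutation test over a sensor array.

    ``cond_a`` and ``cond_b`` are participants x sensors scalars (e.g.
    coherence at the tagging frequency in the stimulation vs baseline
    interval).  Per sensor a Wilcoxon signed-rank z is computed; sensors
    with two-sided p below ``cluster_alpha`` are clustered by adjacency
    separately by sign, and each cluster's mass (sum of z) is compared
    against the null distribution of the maximum |mass| over random
    participant-wise condition-label flips.  With 11 participants and
    ``n_perm >= 2048`` the 2^11 sign assignments are enumerated exactly.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("cond_a and cond_b must be participants x sensors arrays")
    n_part, n_sens = a.shape
    if n_part < 2:
        raise ValueError("need at least 2 participants")
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != (n_sens, n_sens):
        raise ValueError(f"adjacency must be {n_sens} x {n_sens}")
    if not np.array_equal(adjacency, adjacency.T) or adjacency.diagonal().any():
        raise ValueError("adjacency must be symmetric with an empty diagonal")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value resolution",
                      stacklevel=2)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diffs = a - b
    ranks_T, sd = _signed_rank_T(diffs)
    safe_sd = np.where(sd > 0, sd, np.inf)
    z_obs = ranks_T / safe_sd
    z_crit = sps.norm.ppf(1 - cluster_alpha / 2)

    adj_sparse = csr_matrix(adjacency)
    observed = _clusters_from_z(z_obs, z_crit, adj_sparse)

    signs, enumerated = _sign_matrix(n_part, n_perm, rng, enumerate_when_possible=True)
    # under sign flips the ranks of |d| are unchanged; only signs enter T
    absd = np.abs(diffs)
    ranks = sps.rankdata(absd, axis=0)
    nz = absd > 0
    ranks = np.where(nz, ranks - (~nz).sum(axis=0), 0.0)
    signed_ranks = np.sign(diffs) * ranks              # part x sens
    z_perm_all = (signs @ signed_ranks) / safe_sd      # perm x sens

    null_max = np.zeros(signs.shape[0])
    for k in range(signs.shape[0]):
        clusters_k = _clusters_from_z(z_perm_all[k], z_crit, adj_sparse)
        if clusters_k:
            null_max[k] = max(abs(m) for _, m in clusters_k)

    n_eff = signs.shape[0]
    clusters = []
    for members, mass in observed:
        if enumerated:
            p = float(np.mean(null_max >= abs(mass) - 1e-12))
        else:
            p = float((1 + np.sum(null_max >= abs(mass) - 1e-12)) / (1 + n_eff))
        clusters.append(Cluster(sensors=tuple(int(i) for i in members),
                                mass=mass, p_value=p))
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterTestResult(clusters=clusters, z_values=z_obs,
                             n_permutations=n_eff, alpha=alpha,
                             cluster_alpha=cluster_alpha, enumerated=enumerated)


# ---------------------------------------------------------------------------
# Participant-level permutation criterion


@dataclass(frozen=True)
class ParticipantPermResult:
    observed: float
    null_quantile_95: float
    p_value: float
    significant: bool
    n_permutations: int
    baseline_observed: float = float("nan")


def _mean_coherence(meg: np.ndarray, diode: np.ndarray, take: np.ndarray) -> float:
    coh, _ = coherence_from_coeffs(meg[take], diode[take])
    return float(np.nanmean(coh))


def participant_permutation_test(
    baseline_coeffs: TrialCoefficients,
    stim_coeffs: TrialCoefficients,
    sensor_set: list[str],
    tag_freq_hz: float,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> ParticipantPermResult:
    """Single-participant tagging-response criterion.

    The observed statistic is the mean stimulation-interval coherence at the
    tagging frequency over ``sensor_set``.  Each permutation shuffles the
    baseline/stimulation trial labels (preserving group sizes), recomputes
    the coherence from the pooled per-trial Fourier coefficients, and takes
    the same mean.  The response is significant when the observed statistic
    strictly exceeds the 95th percentile of the permuted statistics —
    one-sided by design, since only a coherence increase indicates tagging.
    """
    if not sensor_set:
        raise ValueError("sensor_set is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _extract(tc: TrialCoefficients) -> tuple[np.ndarray, np.ndarray]:
        fi = freq_index(tc.freqs_hz, tag_freq_hz)
        ids = tc.channel_ids
        sidx = [ids.index(s) for s in sensor_set]
        return tc.coeffs[:, sidx, fi], tc.coeffs[:, tc.photodiode_index, fi]

    meg_b, dio_b = _extract(baseline_coeffs)
    meg_s, dio_s = _extract(stim_coeffs)
    n_b, n_s = meg_b.shape[0], meg_s.shape[0]
    if n_b < 2 or n_s < 2:
        raise ValueError("need at least 2 trials per interval")

    meg = np.concatenate([meg_b, meg_s])[:, :, None]   # trials x sens x 1 bin
    dio = np.concatenate([dio_b, dio_s])[:, None]
    observed = _mean_coherence(meg, dio, np.arange(n_b, n_b + n_s))
    baseline_obs = _mean_coherence(meg, dio, np.arange(n_b))

    perm_stats = np.empty(n_perm)
    n_tot = n_b + n_s
    for k in range(n_perm):
        order = rng.permutation(n_tot)
        perm_stats[k] = _mean_coherence(meg, dio, order[n_b:])

    q95 = float(np.quantile(perm_stats, 0.95))
    p = float((1 + np.sum(perm_stats >= observed)) / (1 + n_perm))
    return ParticipantPermResult(observed=observed, null_quantile_95=q95,
                                 p_value=p, significant=bool(observed > q95),
                                 n_permutations=n_perm,
                                 baseline_observed=baseline_obs)


# ---------------------------------------------------------------------------
# Summaries


@dataclass(frozen=True)
class LateralizationResult:
    li: float
    freq_hz: float
    left_coh: float
    right_coh: float


def lateralization_index(coh_left_stim: float, coh_right_stim: float,
                         tag_freq_hz: float = 66.0) -> LateralizationResult:
    """Normalized hemifield contrast LI = (L - R) / (L + R) in [-1, 1].

    ``coh_left_stim`` is the coherence for a left-hemifield patch and
    ``coh_right_stim`` its right-hemifield counterpart, both at the tagging
    frequency.  Undefined (raises) when both inputs are zero.
    """
    for name, v in (("left", coh_left_stim), ("right", coh_right_stim)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} coherence {v} outside [0, 1]")
    total = coh_left_stim + coh_right_stim
    if total == 0:
        raise DegenerateTestError("both coherences are zero; LI undefined")
    li = (coh_left_stim - coh_right_stim) / total
    return LateralizationResult(li=float(li), freq_hz=tag_freq_hz,
                                left_coh=float(coh_left_stim),
                                right_coh=float(coh_right_stim))


def fit_condition_slope(condition_values, coherence_means) -> tuple[float, float]:
    """OLS slope of mean coherence against a condition axis, with its SE.

    Units are coherence per condition unit (per Hz, per degree, ...); scale
    ``condition_values`` beforehand to report per-4-Hz or similar.
    """
    x = np.asarray(condition_values, dtype=float)
    y = np.asarray(coherence_means, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need 1D arrays of equal length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("condition axis is constant; slope undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.stderr)


def proportion_significant(per_participant_results) -> float:
    """Percentage of participants whose permutation criterion was met."""
    flags = [r.significant if isinstance(r, ParticipantPermResult) else bool(r)
             for r in per_participant_results]
    if not flags:
        raise ValueError("no participant results given")
    return 100.0 * sum(flags) / len(flags)
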