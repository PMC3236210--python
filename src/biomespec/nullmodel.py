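"""Richness-constrained Monte Carlo null model for biomic specialization.

The null hypothesis is that biomic specialists are randomly scattered
across biomes and clades.  Each replicate places species into biomes at
random while holding the observed per-biome species richness fixed:
biome *b* receives exactly ``sp_b`` distinct species drawn uniformly
without replacement from the *N* species, independently across biomes.
BSI frequencies are expressed as percentages of the species that occupy
at least one biome in that replicate; per-biome specialist fractions are
the share of each biome's occupants having BSI = 1.

An exact analytic counterpart is provided for verification: under the
null each species occupies biome *b* with probability ``p_b = sp_b/N``
independently across biomes, so its BSI follows a Poisson-binomial
distribution, conditioned on occupying at least one biome; the
probability that an occupant of biome *b* is a specialist is
``prod_{j != b} (1 - p_j)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import BIOME_LABELS
from .coding import PresenceMatrix

DEFAULT_N_REPS = 10_000


@dataclass(frozen=True)
class RichnessMarginals:
    """Observed per-biome species richness ``sp_b`` plus total richness N."""

    counts: tuple[int, ...]
    n_species: int
    labels: tuple[str, ...] = BIOME_LABELS

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.labels):
            raise ValueError(
                f"{len(self.counts)} counts for {len(self.labels)} biomes"
            )
        if self.n_species <= 0:
            raise ValueError("n_species must be positive")
        for lab, c in zip(self.labels, self.counts):
            if not (0 <= c <= self.n_species):
                raise ValueError(
                    f"biome {lab}: richness {c} outside [0, {self.n_species}]"
                )
        if sum(self.counts) == 0:
            raise ValueError("all biome richness values are zero")

    @classmethod
    def from_matrix(cls, matrix: PresenceMatrix) -> "RichnessMarginals":
        rich = matrix.richness
        return cls(tuple(int(v) for v in rich), matrix.n_species,
                   tuple(rich.index))

    @property
    def occupancy_probabilities(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n_species

    @property
    def n_biomes(self) -> int:
        return len(self.counts)


@dataclass
class NullEnsemble:
    """Replicate-level null statistics.

    ``bsi_percent[r, k-1]`` is the percentage of occupied species with
    BSI = k in replicate r; ``specialist_percent[r, b]`` the percentage of
    biome b's occupants with BSI = 1 (NaN where ``sp_b = 0``).
    """

    marginals: RichnessMarginals
    bsi_percent: np.ndarray
    specialist_percent: np.ndarray
    seed: Optional[int]
    occupancy: Optional[np.ndarray] = None   # (n_reps, N, B), on request

    @property
    def n_reps(self) -> int:
        return self.bsi_percent.shape[0]


def simulate_null(
    marginals: RichnessMarginals,
    n_reps: int = DEFAULT_N_REPS,
    seed: Optional[int] = None,
    keep_occupancy: bool = False,
) -> NullEnsemble:
    """Draw ``n_reps`` richness-constrained random placements.

    Vectorized over replicates: for each biome, the ``sp_b`` occupants of
    each replicate are the species with the ``sp_b`` smallest of N iid
    uniform variates (a uniform draw without replacement).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    N = marginals.n_species
    B = marginals.n_biomes
    counts = np.asarray(marginals.counts)

    occ = np.zeros((n_reps, N, B), dtype=bool)
    for b in range(B):
        sp_b = int(counts[b])
        if sp_b == 0:
            continue
        u = rng.random((n_reps, N))
        if sp_b == N:
            occ[:, :, b] = True
            continue
        kth = np.partition(u, sp_b - 1, axis=1)[:, sp_b - 1][:, None]
        occ[:, :, b] = u <= kth

    K = occ.sum(axis=2)                       # per-species BSI, (n_reps, N)
    occupied = (K >= 1).sum(axis=1).astype(float)   # denominator per replicate

    bsi_percent = np.empty((n_reps, B), dtype=float)
    for k in range(1, B + 1):
        bsi_percent[:, k - 1] = (K == k).sum(axis=1) / occupied * 100.0

    specialist_percent = np.full((n_reps, B), np.nan)
    spec = K == 1
    for b in range(B):
        sp_b = int(counts[b])
        if sp_b == 0:
            continue      # undefined, reported as NaN rather than zero
        specialist_percent[:, b] = (
            (occ[:, :, b] & spec).sum(axis=1) / sp_b * 100.0
        )

    return NullEnsemble(marginals, bsi_percent, specialist_percent, seed,
                        occupancy=occ if keep_occupancy else None)


def analytic_null_bsi(marginals: RichnessMarginals) -> dict[str, np.ndarray]:
    """Exact null expectations from the Poisson-binomial distribution.

    Returns ``bsi_pmf`` — P(BSI = k | BSI >= 1) for k = 1..B, computed by
    polynomial convolution over the per-biome occupancy probabilities —
    and ``specialist_prob`` — P(BSI = 1 | occupies b) per biome
    (NaN where ``sp_b = 0``).
    """
    p = marginals.occupancy_probabilities
    pmf = np.array([1.0])
    for pb in p:
        pmf = np.convolve(pmf, [1.0 - pb, pb])
    p_zero = pmf[0]
    if p_zero >= 1.0:
        raise ValueError("all occupancy probabilities are zero")
    bsi_pmf = pmf[1:] / (1.0 - p_zero)

    specialist = np.full(marginals.n_biomes, np.nan)
    for b in range(marginals.n_biomes):
        if marginals.counts[b] == 0:
            continue
        others = np.delete(p, b)
        specialist[b] = np.prod(1.0 - others)
    return {"bsi_pmf": bsi_pmf, "specialist_prob": specialist}


@dataclass(frozen=True)
class PValue:
    """Two one-sided empirical p-values with inclusive counting.

    ``upper`` = P(null >= observed), ``lower`` = P(null <= observed);
    ``direction`` names the reported tail.  Exact fractions are stored;
    ``display`` renders values below 1/n_reps as ``"<0.001"``-style
    strings, matching the usual reporting convention.
    """

    upper: float
    lower: float
    direction: str
    n_reps: int

    @property
    def value(self) -> float:
        return self.upper if self.direction == "upper" else self.lower

    @property
    def display(self) -> str:
        v = self.value
        floor = 1.0 / self.n_reps
        if v < max(floor, 1e-3):
            thr = max(floor, 1e-3)
            return f"<{thr:.3g}"
        return f"{v:.3f}"


def empirical_pvalue(
    observed: float,
    null_values: Sequence[float] | np.ndarray,
    direction: str = "auto",
) -> PValue:
    """Empirical p-value of an observed percentage against null replicates.

    Counting is inclusive (>= / <=) with no pseudo-count.  ``auto`` picks
    the upper tail when the observed value exceeds the null mean, else the
    lower tail.
    """
    null_values = np.asarray(null_values, dtype=float)
    null_values = null_values[~np.isnan(null_values)]
    if null_values.size == 0:
        raise ValueError("empty null ensemble")
    n = null_values.size
    upper = float((null_values >= observed).sum()) / n
    lower = float((null_values <= observed).sum()) / n
    if direction == "auto":
        direction = "upper" if observed > null_values.mean() else "lower"
    elif direction not in ("upper", "lower"):
        raise ValueError(f"direction must be upper/lower/auto, got {direction!r}")
    return PValue(upper=upper, lower=lower, direction=direction, n_reps=n)


def _summary_row(observed: float, null: np.ndarray) -> dict:
    null = null[~np.isnan(null)]
    if null.size == 0:
        return {
            "observed_pct": observed, "null_mean": np.nan, "null_sd": np.nan,
            "null_min": np.nan, "null_max": np.nan,
            "p_upper": np.nan, "p_lower": np.nan, "p": np.nan,
            "tail": "undefined", "p_display": "NA",
        }
    pv = empirical_pvalue(observed, null)
    return {
        "observed_pct": observed,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)) if null.size > 1 else 0.0,
        "null_min": float(null.min()),
        "null_max": float(null.max()),
        "p_upper": pv.upper,
        "p_lower": pv.lower,
        "p": pv.value,
        "tail": pv.direction,
        "p_display": pv.display,
    }


def bsi_null_summary(
    observed_bsi: pd.Series, ensemble: NullEnsemble
) -> pd.DataFrame:
    """Observed vs null BSI frequency table (one row per BSI value 1..B).

    ``observed_bsi`` holds per-species BSI counts; percentages use the
    number of species as denominator.
    """
    B = ensemble.marginals.n_biomes
    n = len(observed_bsi)
    if n == 0:
        raise ValueError("no species in observed BSI vector")
    rows = {}
    for k in range(1, B + 1):
        obs_pct = float((observed_bsi == k).sum()) / n * 100.0
        rows[k] = _summary_row(obs_pct, ensemble.bsi_percent[:, k - 1])
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "bsi"
    return out


def biome_specialist_summary(
    matrix: PresenceMatrix, ensemble: NullEnsemble
) -> pd.DataFrame:
    """Observed vs null per-biome specialist fractions (Table-style).

    For each biome: total occupants, observed specialist count and
    percentage, and the null mean/sd/range and p-value of the percentage
    of occupants having BSI = 1.  Biomes with no occupants are reported
    with NaN statistics (undefined, not zero).
    """
    bsi = matrix.data.sum(axis=1)
    spec = bsi == 1
    rows = {}
    for b, label in enumerate(ensemble.marginals.labels):
        sp_b = int(ensemble.marginals.counts[b])
        present = matrix.data[label]
        n_spec = int((present & spec).sum())
        obs_pct = n_spec / sp_b * 100.0 if sp_b > 0 else np.nan
        row = {"sp": sp_b, "sp_bsi1": n_spec}
        if sp_b > 0:
            row.update(_summary_row(obs_pct, ensemble.specialist_percent[:, b]))
        else:
            row.update(_summary_row(np.nan, np.array([np.nan])))
        rows[label] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "biome"
    return out


@dataclass
class NullAnalysis:
    """Bundle of the observed-vs-null summaries for one species set."""

    marginals: RichnessMarginals
    bsi_table: pd.DataFrame
    biome_table: pd.DataFrame
    n_reps: int
    seed: Optional[int]


def run_null_analysis(
    matrix: PresenceMatrix,
    clade: Optional[str] = None,
    n_reps: int = DEFAULT_N_REPS,
    seed: Optional[int] = None,
) -> NullAnalysis:
    """Full null analysis for an assemblage or a single clade.

    With ``clade`` given, the matrix is restricted to that clade and the
    richness marginals are recomputed on the restricted matrix (clade
    analyses randomize clade members only, against clade-level richness).
    """
    if clade is not None:
        matrix = matrix.for_clade(clade)
    if matrix.n_species == 0:
        raise ValueError("presence matrix is empty")
    marginals = RichnessMarginals.from_matrix(matrix)
    ensemble = simulate_null(marginals, n_reps=n_reps, seed=seed)
    observed_bsi = matrix.data.sum(axis=1)
    return NullAnalysis(
        marginals=marginals,
        bsi_table=bsi_null_summary(observed_bsi, ensemble),
        biome_table=biome_specialist_summary(matrix, ensemble),
        n_reps=n_reps,
        seed=seed,
    )
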