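"""Calibration-informed variability characterization and cohort simulation.

The generative model treats a simulated measurement as a statistical variable

    Y = x_k + f_1 + f_2 + ... + f_M

where ``x_k`` is an experimental *seed* spectrum and each ``f`` is a random
perturbation built from one empirically characterized variability source.
A source is a set of *calibration difference vectors* ``d_j``: either
mean-centered deviations of repeated measurements of one material
(``d_j = u_j - u_bar``) or index-paired differences between two measurement
conditions (``d_j = u_j - v_j``, e.g. serum minus plasma of the same blood
draw).

A draw from a source with ``m`` difference vectors is

    f = shift + (lambda / sqrt(m)) * sum_j c_j * d~_j,      c_j ~ N(0, 1)

so that at scale ``lambda = 1`` the injected covariance equals the empirical
second-moment matrix of the differences, ``(1/m) sum_j d~_j d~_j^T``, making
``lambda`` an interpretable multiple of the observed variability. For paired
sources an optional deterministic component ``shift = alpha * d_bar`` moves a
seed along the mean paired difference (``alpha`` fixed, or Uniform(0,1) per
draw to emulate mixtures between two measurement conditions); the residual
differences are then centered (``d~_j = d_j - d_bar``) so the stochastic part
stays zero-mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AxisMismatchError,
    InsufficientCalibrationError,
    InsufficientDataError,
    PairingError,
    ParameterError,
)
from .spectra_io import SpectraSet, SpectralAxis, assert_same_axis


@dataclass
class DifferenceSet:
    """Matrix of calibration difference vectors defining one variability source."""

    axis: SpectralAxis
    diffs: np.ndarray
    mode: str  # "mean_centered" | "paired"
    source_name: str = ""

    def __post_init__(self):
        self.diffs = np.atleast_2d(np.asarray(self.diffs, dtype=float))
        if self.mode not in ("mean_centered", "paired"):
            raise ParameterError(f"unknown difference mode {self.mode!r}")
        m, p = self.diffs.shape
        if m < 1 or (self.mode == "mean_centered" and m < 2):
            raise InsufficientCalibrationError(
                f"source {self.source_name!r}: need >= 2 calibration rows, got {m}"
            )
        if p != self.axis.n_channels:
            raise AxisMismatchError("difference vectors do not match axis length")
        if not np.all(np.isfinite(self.diffs)):
            raise ParameterError("difference vectors must be finite")
        if self.mode == "mean_centered":
            colsum = np.abs(self.diffs.sum(axis=0)).max()
            limit = 1e-9 * m * max(np.abs(self.diffs).max(), 1.0)
            if colsum > limit:
                raise ParameterError(
                    f"mean_centered differences must sum to zero (|sum| = {colsum:.3g})"
                )
        if not self.diffs.any():
            warnings.warn(
                f"variability source {self.source_name!r} has all-zero differences; "
                "it will inject nothing",
                stacklevel=2,
            )

    @property
    def m(self) -> int:
        return self.diffs.shape[0]


@dataclass
class VariabilitySource:
    """A difference set plus its variance multiplier and optional mean shift.

    ``scale`` multiplies the injected standard deviation: the injected
    covariance is ``scale**2`` times the empirical second moment of the
    (centered) differences. ``shift_mode`` is only meaningful for paired
    difference sets, where the mean paired difference encodes a systematic
    offset between two measurement conditions.
    """

    diffset: DifferenceSet
    scale: float = 1.0
    shift_mode: str = "none"  # "none" | "fixed" | "uniform"
    shift_alpha: float = 1.0

    def __post_init__(self):
        if self.scale < 0:
            raise ParameterError("scale must be nonnegative")
        if self.shift_mode not in ("none", "fixed", "uniform"):
            raise ParameterError(f"unknown shift_mode {self.shift_mode!r}")
        if self.shift_mode != "none" and self.diffset.mode != "paired":
            raise ParameterError("shift_mode requires a paired difference set")
        if self.shift_mode == "fixed" and not (0.0 <= self.shift_alpha <= 1.0):
            raise ParameterError("shift_alpha must lie in [0, 1]")

    def with_scale(self, scale: float) -> "VariabilitySource":
        return VariabilitySource(self.diffset, scale, self.shift_mode, self.shift_alpha)

    def _centered(self) -> tuple[np.ndarray, np.ndarray]:
        """(d~ matrix, mean difference) per the shift convention."""
        d = self.diffset.diffs
        if self.shift_mode == "none":
            return d, np.zeros(d.shape[1])
        dbar = d.mean(axis=0)
        return d - dbar, dbar

    def injected_covariance(self) -> np.ndarray:
        """Closed-form covariance of one draw from this source.

        ``scale**2 * (1/m) * sum_j d~_j d~_j^T``, plus ``Var(alpha) * dbar dbar^T``
        (= 1/12) for the stochastic uniform-mixture shift.
        """
        dt, dbar = self._centered()
        m = self.diffset.m
        cov = (self.scale**2 / m) * dt.T @ dt
        if self.shift_mode == "uniform":
            cov = cov + np.outer(dbar, dbar) / 12.0
        return cov

    def injected_std(self) -> np.ndarray:
        """Per-channel standard deviation of one draw (sqrt of cov diagonal)."""
        dt, dbar = self._centered()
        var = (self.scale**2 / self.diffset.m) * (dt**2).sum(axis=0)
        if self.shift_mode == "uniform":
            var = var + dbar**2 / 12.0
        return np.sqrt(var)


@dataclass
class SimulationConfig:
    """Everything needed to generate one simulated cohort reproducibly.

    ``seeds`` are the experimental training spectra (one or more per class),
    ``sources`` the ordered variability sources (order is part of the
    reproducibility contract), ``n_per_seed`` the number of simulated
    measurements generated per seed, and ``rng_seed`` the generator seed.
    """

    seeds: SpectraSet
    sources: list[VariabilitySource] = field(default_factory=list)
    n_per_seed: int = 1000
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_per_seed < 1:
            raise ParameterError("n_per_seed must be >= 1")
        for src in self.sources:
            if not assert_same_axis(self.seeds.axis, src.diffset.axis):
                raise AxisMismatchError(
                    f"source {src.diffset.source_name!r} axis differs from seeds"
                )


def differences_mean_centered(u: SpectraSet, source_name: str = "") -> DifferenceSet:
    """Deviations of each calibration measurement from the set mean.

    Suits repeated measurements of one stable material (QC pools, water
    blanks) whose scatter around its mean is the variability of interest.
    """
    if u.n < 2:
        raise InsufficientCalibrationError(
            f"need >= 2 calibration measurements, got {u.n}"
        )
    return DifferenceSet(
        axis=u.axis,
        diffs=u.data - u.data.mean(axis=0),
        mode="mean_centered",
        source_name=source_name,
    )


def differences_paired(u: SpectraSet, v: SpectraSet, source_name: str = "") -> DifferenceSet:
    """Index-paired differences ``u_j - v_j`` between two measurement conditions.

    Pairing is positional: row ``j`` of ``u`` and row ``j`` of ``v`` must be
    the same underlying sample measured under the two conditions.
    """
    if not assert_same_axis(u, v):
        raise AxisMismatchError("paired sets must share a spectral axis")
    if u.n != v.n:
        raise PairingError(f"pair count mismatch: {u.n} vs {v.n}")
    return DifferenceSet(
        axis=u.axis, diffs=u.data - v.data, mode="paired", source_name=source_name
    )


def differences_within_subject(u: SpectraSet, source_name: str = "") -> DifferenceSet:
    """Pooled per-subject mean-centered deviations from a longitudinal set.

    Each subject's repeated measurements are centered on that subject's own
    mean, so the pooled differences characterize within-person variability
    over time while discarding between-person offsets. Subjects with a single
    measurement contribute nothing and are dropped.
    """
    subjects = u.meta["subject"].to_numpy()
    blocks = []
    for subj in np.unique(subjects):
        rows = u.data[subjects == subj]
        if rows.shape[0] >= 2:
            blocks.append(rows - rows.mean(axis=0))
    if not blocks:
        raise InsufficientCalibrationError(
            "no subject has >= 2 measurements to center"
        )
    diffs = np.vstack(blocks)
    # centering is per subject, so the pooled column sums are exactly zero too
    return DifferenceSet(axis=u.axis, diffs=diffs, mode="mean_centered",
                         source_name=source_name)


def _sample_block(src: VariabilitySource, n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent draws from one source, stacked as rows.

    Draw order (normals first, then mixture coefficients for uniform shift)
    is fixed and part of the reproducibility contract.
    """
    dt, dbar = src._centered()
    m = src.diffset.m
    c = rng.standard_normal((n, m))
    out = (src.scale / np.sqrt(m)) * (c @ dt)
    if src.shift_mode == "fixed":
        out += src.shift_alpha * dbar
    elif src.shift_mode == "uniform":
        alphas = rng.uniform(size=n)
        out += alphas[:, None] * dbar
    return out


def sample_perturbation(src: VariabilitySource, rng: np.random.Generator) -> np.ndarray:
    """One draw ``f = shift + (scale/sqrt(m)) * sum_j c_j d~_j`` from a source."""
    return _sample_block(src, 1, rng)[0]


def generate_cohort(cfg: SimulationConfig) -> SpectraSet:
    """Simulate a cohort by adding independent source draws to every seed.

    Output rows are seed-major: all ``n_per_seed`` replicates of seed 0, then
    seed 1, and so on. Each replicate is the seed plus one fresh draw per
    source; labels and subject metadata are copied from the seed and
    provenance is set to ``"simulated"``. With all sources at scale 0 and no
    shift the output rows are bit-exact copies of the seeds. Identical
    configs (including ``rng_seed``) reproduce the cohort bit-identically.
    """
    seeds, n_rep = cfg.seeds, cfg.n_per_seed
    rng = np.random.default_rng(cfg.rng_seed)
    n_total = seeds.n * n_rep
    data = np.repeat(seeds.data, n_rep, axis=0)
    for src in cfg.sources:
        data += _sample_block(src, n_total, rng)
    labels = np.repeat(seeds.labels, n_rep)
    meta = seeds.meta.loc[seeds.meta.index.repeat(n_rep)].reset_index(drop=True)
    meta["provenance"] = "simulated"
    return SpectraSet(axis=seeds.axis, data=data, labels=labels, meta=meta)


def std_profile(s: SpectraSet) -> np.ndarray:
    """Unbiased (n-1 denominator) per-channel standard deviation of a set.

    The canonical readout for comparing the spread of a simulated cohort
    against the spread injected by each individual variability source.
    """
    if s.n < 2:
        raise InsufficientDataError("std_profile needs >= 2 measurements")
    return s.data.std(axis=0, ddof=1)
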