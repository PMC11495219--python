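"""Synthetic blood-IR-like fingerprint scenarios with controllable variability.

Generates cohorts of 1-D absorption spectra whose variability structure
mirrors what longitudinal IR fingerprinting studies observe: stable
person-specific band patterns, slow within-person biological change across
visits, smooth instrument/session drift, multiplicative gain scatter, white
detector noise, a systematic offset between two instrument states (train vs.
test measurement campaigns), and fixed spectral offsets between specimen
types (plasma-like vs. serum-like). None of this claims physical fidelity;
it reproduces the *statistical* structure the augmentation framework is
designed to characterize, so every experiment and test can run without
external data.

Scenario layout: the first ``n_baseline_visits`` visits of each study subject
are measured under instrument state A and form the training pool; the
remaining visits are measured under state B (state offset plus fresh session
draws) and form the test set. Calibration sets come from held-out subjects,
a QC-like constant material and blank spectra, measured under both states, so
characterized variability never involves train/test subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import ParameterError, LeakageError
from .spectra_io import SpectraSet, SpectralAxis


@dataclass
class BandModel:
    """Gaussian absorption bands: positions (cm^-1), widths (cm^-1), heights (a.u.)."""

    centers: np.ndarray
    widths: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if not (self.centers.shape == self.widths.shape == self.amplitudes.shape):
            raise ParameterError("band arrays must have equal lengths")
        if np.any(self.widths <= 0):
            raise ParameterError("band widths must be positive")
        if np.any(self.amplitudes < 0):
            raise ParameterError("band amplitudes must be nonnegative")

    @property
    def n_bands(self) -> int:
        return self.centers.size


def default_bands() -> BandModel:
    """Twelve bands echoing the major blood-spectrum features.

    Positions roughly follow the fingerprint and C-H stretch regions (amide
    I/II, lipid ester, carbohydrate C-O, CH2/CH3 stretches); amplitudes span
    [0.1, 1.0] a.u.
    """
    return BandModel(
        centers=np.array([1080, 1170, 1245, 1310, 1400, 1455,
                          1550, 1655, 1740, 2855, 2930, 2960], dtype=float),
        widths=np.array([30, 25, 28, 22, 20, 18,
                         32, 28, 16, 14, 18, 12], dtype=float),
        amplitudes=np.array([0.30, 0.15, 0.25, 0.12, 0.28, 0.35,
                             0.70, 1.00, 0.18, 0.22, 0.40, 0.10]),
    )


def default_case_effect() -> np.ndarray:
    """Fixed per-band amplitude deltas of the synthetic disease phenotype.

    Elevates the carboxylate, lipid-ester and CH2-stretch bands and slightly
    depresses amide I, at a size well below the between-person amplitude
    scatter, so detection is possible but not trivial.
    """
    delta = np.zeros(12)
    delta[[4, 7, 8, 10]] = np.array([0.9, -0.5, 0.7, 0.4]) * 0.015
    return delta


def default_specimen_offset() -> BandModel:
    """Fixed plasma-vs-serum spectral offset (anticoagulant-related features).

    Centered on carboxylate/protein regions where EDTA plasma and clotted
    serum differ; peak offset height 0.10 a.u. against a base spectrum of
    height 1.0.
    """
    return BandModel(
        centers=np.array([1100.0, 1250.0, 1400.0, 1590.0, 1730.0]),
        widths=np.array([35.0, 30.0, 25.0, 28.0, 18.0]),
        amplitudes=np.array([0.04, 0.03, 0.09, 0.10, 0.05]),
    )


def make_base_spectrum(axis: SpectralAxis, bands: BandModel) -> np.ndarray:
    """Sum of Gaussian bands evaluated on the axis (zero bands -> zero vector)."""
    if bands.n_bands == 0:
        return np.zeros(axis.n_channels)
    return bands.amplitudes @ _band_matrix(axis, bands)


def _band_matrix(axis: SpectralAxis, bands: BandModel) -> np.ndarray:
    """Unit-amplitude band shapes, n_bands x n_channels."""
    w = axis.values[None, :]
    c = bands.centers[:, None]
    s = bands.widths[:, None]
    return np.exp(-0.5 * ((w - c) / s) ** 2)


@dataclass
class PopulationConfig:
    """Knobs of the synthetic population generator.

    Magnitudes are in absorbance units against a base spectrum of peak height
    1.0 a.u. ``between_person_sd`` and ``within_person_sd`` act on band
    amplitudes (lognormal multiplicative perturbation per individual, and a
    lognormal random-walk step per visit, respectively). ``drift_sd`` sets
    the size of the smooth per-measurement session baseline; ``noise_sd`` the
    white channel noise; ``gain_sd`` the multiplicative scatter of the whole
    spectrum; ``state_shift`` the magnitude of the fixed smooth offset that
    separates the test-campaign instrument state from the training one.
    """

    axis_range: tuple = (1000.0, 3000.0)
    n_channels: int = 500
    n_individuals: int = 32
    n_visits: int = 4
    n_baseline_visits: int = 1
    bands: BandModel = field(default_factory=default_bands)
    between_person_sd: float = 0.18
    within_person_sd: float = 0.035
    drift_sd: float = 0.015
    drift_smoothness: float = 40.0
    noise_sd: float = 0.004
    gain_sd: float = 0.01
    state_shift: float = 0.015
    study_offset_sd: float = 0.02
    n_studies: int = 3
    n_latent_factors: int = 4
    case_effect: np.ndarray | None = None
    specimen_offset: BandModel | None = None
    specimen_attenuation: float = 1.0
    n_calib_subjects: int = 12
    n_calib_visits: int = 6
    n_qc: int = 48
    n_replicates: int = 48
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("between_person_sd", "within_person_sd", "drift_sd",
                     "noise_sd", "gain_sd", "state_shift", "study_offset_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_individuals < 1 or self.n_visits < 1:
            raise ParameterError("need n_individuals >= 1 and n_visits >= 1")
        if not (1 <= self.n_baseline_visits <= self.n_visits):
            raise ParameterError("n_baseline_visits must lie in [1, n_visits]")
        if self.case_effect is not None:
            self.case_effect = np.asarray(self.case_effect, dtype=float)
            if self.case_effect.shape != (self.bands.n_bands,):
                raise ParameterError("case_effect needs one delta per band")

    @property
    def axis(self) -> SpectralAxis:
        lo, hi = self.axis_range
        return SpectralAxis(np.linspace(lo, hi, self.n_channels))


@dataclass
class ScenarioDataset:
    """One synthetic study: train/test splits plus leakage-safe calibration sets.

    ``calib_longitudinal`` holds repeated visits of held-out subjects,
    ``calib_qc`` repeated measurements of a constant pooled material,
    ``calib_replicates`` blank (noise-only) measurements, and
    ``calib_specimen_pairs`` index-paired (plasma-like, serum-like)
    measurements from further held-out subjects. ``test_serum`` is the
    serum-like rendering of the test measurements, present only in
    cross-specimen scenarios. Calibration subjects are disjoint from
    train/test subjects by construction, and verified here.
    """

    train: SpectraSet
    test: SpectraSet
    calib_qc: SpectraSet
    calib_replicates: SpectraSet
    calib_longitudinal: SpectraSet
    calib_specimen_pairs: tuple | None = None
    test_serum: SpectraSet | None = None
    config: PopulationConfig | None = None

    def __post_init__(self):
        study = set(self.train.subjects()) | set(self.test.subjects())
        calib = set(self.calib_longitudinal.subjects())
        if self.calib_specimen_pairs is not None:
            calib |= set(self.calib_specimen_pairs[0].subjects())
        overlap = study & calib
        if overlap:
            raise LeakageError(f"calibration subjects overlap study subjects: {sorted(overlap)}")


def _smooth_curve(rng: np.random.Generator, n_channels: int, sd: float,
                  smoothness: float) -> np.ndarray:
    """Random cubic trend plus low-pass-filtered noise, overall scale ``sd``."""
    if sd == 0.0:
        return np.zeros(n_channels)
    t = np.linspace(-1.0, 1.0, n_channels)
    coeffs = rng.standard_normal(4)
    cubic = coeffs[0] + coeffs[1] * t + coeffs[2] * t**2 + coeffs[3] * t**3
    rough = gaussian_filter1d(rng.standard_normal(n_channels), smoothness, mode="nearest")
    rough_sd = rough.std()
    if rough_sd > 0:
        rough = rough / rough_sd
    return sd * (0.7 * cubic / np.sqrt(coeffs @ coeffs + 1e-12) * 2.0 + 0.5 * rough)


class _Instrument:
    """Session-level measurement machinery shared by all generated sets."""

    def __init__(self, cfg: PopulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.axis = cfg.axis
        self.G = _band_matrix(self.axis, cfg.bands)
        # fixed offset between instrument state A (training campaign) and
        # state B (test campaign); drawn once per scenario
        self.state_offset = _smooth_curve(rng, cfg.n_channels, cfg.state_shift,
                                          cfg.drift_smoothness)
        # per-study collection/handling offsets; study 0 is the scenario's
        # own study and defines the reference protocol
        self.study_offsets = [np.zeros(cfg.n_channels)] + [
            _smooth_curve(rng, cfg.n_channels, cfg.study_offset_sd, cfg.drift_smoothness)
            for _ in range(max(cfg.n_studies - 1, 0))
        ]
        # biological variation acts through a few latent physiological
        # factors; loadings map factor space onto band log-amplitudes
        k = max(min(cfg.n_latent_factors, cfg.bands.n_bands), 1) if cfg.bands.n_bands else 1
        L = rng.standard_normal((cfg.bands.n_bands, k)) if cfg.bands.n_bands else np.zeros((0, k))
        norms = np.linalg.norm(L, axis=0)
        self.loadings = L / np.where(norms > 0, norms, 1.0) * np.sqrt(cfg.bands.n_bands / k if k else 1.0)

    def measure(self, amplitudes: np.ndarray, state: str, study: int = 0) -> np.ndarray:
        cfg, rng = self.cfg, self.rng
        pure = amplitudes @ self.G
        gain = 1.0 + cfg.gain_sd * rng.standard_normal()
        drift = _smooth_curve(rng, cfg.n_channels, cfg.drift_sd, cfg.drift_smoothness)
        noise = cfg.noise_sd * rng.standard_normal(cfg.n_channels)
        y = gain * pure + drift + noise + self.study_offsets[study]
        if state == "B":
            y = y + self.state_offset
        return y

    def measure_serum(self, amplitudes: np.ndarray, state: str) -> np.ndarray:
        """Serum-like rendering: attenuated spectrum plus the specimen offset."""
        cfg = self.cfg
        offset = make_base_spectrum(self.axis, cfg.specimen_offset)
        pure = cfg.specimen_attenuation * (amplitudes @ self.G) + offset
        gain = 1.0 + cfg.gain_sd * self.rng.standard_normal()
        drift = _smooth_curve(self.rng, cfg.n_channels, cfg.drift_sd, cfg.drift_smoothness)
        noise = cfg.noise_sd * self.rng.standard_normal(cfg.n_channels)
        y = gain * pure + drift + noise
        if state == "B":
            y = y + self.state_offset
        return y


def _amplitude_walk(inst: "_Instrument", n_visits: int,
                    extra: np.ndarray | None = None) -> np.ndarray:
    """Per-visit band amplitudes: latent-factor person effect then a random walk.

    The person effect and the visit-to-visit walk both act in the latent
    factor space and map to band log-amplitudes through the scenario's fixed
    loading matrix, so biological variation is low-rank as in real biofluids.
    """
    cfg, rng, L = inst.cfg, inst.rng, inst.loadings
    nb = cfg.bands.n_bands
    k = L.shape[1]
    a0 = cfg.bands.amplitudes * np.exp(cfg.between_person_sd * (L @ rng.standard_normal(k)))
    if extra is not None:
        a0 = np.clip(a0 + extra, 0.0, None)
    amps = np.empty((n_visits, nb))
    amps[0] = a0
    for t in range(1, n_visits):
        amps[t] = amps[t - 1] * np.exp(cfg.within_person_sd * (L @ rng.standard_normal(k)))
    return amps


def _as_set(axis, rows, labels, subjects, visits, specimen="plasma",
            batches=None, provenance="experimental") -> SpectraSet:
    n = len(rows)
    data = np.vstack(rows) if n else np.empty((0, axis.n_channels))
    if batches is None:
        batches = [""] * n
    meta = pd.DataFrame({
        "id": [f"m{i}" for i in range(n)],
        "subject": list(subjects),
        "visit": [str(v) for v in visits],
        "specimen": [specimen] * n,
        "batch": [str(b) for b in batches],
        "provenance": [provenance] * n,
    })
    return SpectraSet(axis=axis, data=data, labels=np.array(labels, dtype=str),
                      meta=meta)


def _calibration_sets(cfg: PopulationConfig, inst: _Instrument):
    """Held-out-subject, QC and blank calibration sets spanning both states."""
    rng, axis = inst.rng, inst.axis
    rows, labels, subjects, visits, batches = [], [], [], [], []
    for i in range(cfg.n_calib_subjects):
        amps = _amplitude_walk(inst, cfg.n_calib_visits)
        for t in range(cfg.n_calib_visits):
            state = "A" if t % 2 == 0 else "B"
            study = t % max(cfg.n_studies, 1)
            rows.append(inst.measure(amps[t], state, study))
            labels.append(f"C{i:03d}")
            subjects.append(f"C{i:03d}")
            visits.append(t)
            batches.append(f"study{study}:{state}")
    calib_long = _as_set(axis, rows, labels, subjects, visits, batches=batches)

    qc_states = ["A" if k < cfg.n_qc // 2 else "B" for k in range(cfg.n_qc)]
    rows = [inst.measure(cfg.bands.amplitudes, st) for st in qc_states]  # constant pooled material
    calib_qc = _as_set(axis, rows, ["QC"] * cfg.n_qc, ["QC"] * cfg.n_qc,
                       range(cfg.n_qc), specimen="qc",
                       batches=[f"study0:{st}" for st in qc_states])

    zero = np.zeros(cfg.bands.n_bands)
    rows = [inst.measure(zero, "A") for _ in range(cfg.n_replicates)]
    calib_rep = _as_set(axis, rows, ["BLANK"] * cfg.n_replicates,
                        ["BLANK"] * cfg.n_replicates, range(cfg.n_replicates),
                        specimen="blank")
    return calib_long, calib_qc, calib_rep


def make_population(cfg: PopulationConfig, n_specimen_pairs: int = 0) -> ScenarioDataset:
    """Generate a longitudinal identification scenario.

    Per individual, visit amplitudes follow a random walk started from a
    person-specific perturbation of the base bands. The first
    ``n_baseline_visits`` visits (state A) form the training set; the
    remaining visits (state B) the test set. Labels are subject identifiers.
    Fully reproducible from ``cfg.rng_seed``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    inst = _Instrument(cfg, rng)
    axis = inst.axis

    tr_rows, tr_lab, tr_sub, tr_vis = [], [], [], []
    te_rows, te_lab, te_sub, te_vis = [], [], [], []
    se_rows, se_lab, se_sub, se_vis = [], [], [], []
    want_serum = cfg.specimen_offset is not None
    for i in range(cfg.n_individuals):
        sid = f"S{i:04d}"
        amps = _amplitude_walk(inst, cfg.n_visits)
        for t in range(cfg.n_visits):
            if t < cfg.n_baseline_visits:
                tr_rows.append(inst.measure(amps[t], "A"))
                tr_lab.append(sid); tr_sub.append(sid); tr_vis.append(t)
            else:
                te_rows.append(inst.measure(amps[t], "B"))
                te_lab.append(sid); te_sub.append(sid); te_vis.append(t)
                if want_serum:
                    se_rows.append(inst.measure_serum(amps[t], "B"))
                    se_lab.append(sid); se_sub.append(sid); se_vis.append(t)

    train = _as_set(axis, tr_rows, tr_lab, tr_sub, tr_vis,
                    batches=["study0:A"] * len(tr_rows))
    test = _as_set(axis, te_rows, te_lab, te_sub, te_vis,
                   batches=["study0:B"] * len(te_rows))
    test_serum = (_as_set(axis, se_rows, se_lab, se_sub, se_vis, specimen="serum",
                          batches=["study0:B"] * len(se_rows))
                  if want_serum else None)

    calib_long, calib_qc, calib_rep = _calibration_sets(cfg, inst)

    pairs = None
    if want_serum and n_specimen_pairs > 0:
        pairs = make_paired_specimens(cfg, n_specimen_pairs, rng=rng, inst=inst,
                                      subject_prefix="P")

    return ScenarioDataset(train=train, test=test, calib_qc=calib_qc,
                           calib_replicates=calib_rep,
                           calib_longitudinal=calib_long,
                           calib_specimen_pairs=pairs, test_serum=test_serum,
                           config=cfg)


def make_case_control(cfg: PopulationConfig, n_cases: int, n_controls: int) -> ScenarioDataset:
    """Generate a binary case-control scenario with an independent test campaign.

    ``case_effect`` adds per-band amplitude deltas to case subjects. Train
    subjects are measured under state A, a disjoint set of test subjects
    under state B. Calibration sets are class-invariant (held-out healthy
    subjects, QC material, blanks).
    """
    if cfg.case_effect is None:
        raise ParameterError("case_effect must be configured for a case-control scenario")
    rng = np.random.default_rng(cfg.rng_seed)
    inst = _Instrument(cfg, rng)
    axis = inst.axis

    def cohort(n_case, n_ctrl, state, prefix):
        rows, labels, subjects = [], [], []
        for i in range(n_case + n_ctrl):
            is_case = i < n_case
            extra = cfg.case_effect if is_case else None
            amps = _amplitude_walk(inst, 1, extra=extra)
            rows.append(inst.measure(amps[0], state))
            labels.append("case" if is_case else "control")
            subjects.append(f"{prefix}{i:04d}")
        return _as_set(axis, rows, labels, subjects, [0] * len(rows),
                       batches=[f"study0:{state}"] * len(rows))

    train = cohort(n_cases, n_controls, "A", "TR")
    test = cohort(n_cases, n_controls, "B", "TE")
    calib_long, calib_qc, calib_rep = _calibration_sets(cfg, inst)
    return ScenarioDataset(train=train, test=test, calib_qc=calib_qc,
                           calib_replicates=calib_rep,
                           calib_longitudinal=calib_long, config=cfg)


def make_paired_specimens(cfg: PopulationConfig, n_pairs: int,
                          rng: np.random.Generator | None = None,
                          inst: _Instrument | None = None,
                          subject_prefix: str = "P",
                          pair_noise_sd: float | None = None):
    """(plasma-like, serum-like) sets, index-paired by underlying sample.

    Pair j shares one biological spectrum and one measurement session; the
    serum member differs by the fixed specimen-offset spectrum, the
    attenuation factor and independent channel noise of size
    ``pair_noise_sd`` (defaults to ``cfg.noise_sd``). Row order defines the
    pairing, so ``differences_paired(serum, plasma)`` recovers the specimen
    difference directly.
    """
    if cfg.specimen_offset is None:
        raise ParameterError("specimen_offset must be configured for paired specimens")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    if inst is None:
        inst = _Instrument(cfg, rng)
    axis = inst.axis
    if pair_noise_sd is None:
        pair_noise_sd = cfg.noise_sd
    offset = make_base_spectrum(axis, cfg.specimen_offset)
    p_rows, s_rows, subjects = [], [], []
    for j in range(n_pairs):
        amps = _amplitude_walk(inst, 1)
        pure = amps[0] @ inst.G
        gain = 1.0 + cfg.gain_sd * rng.standard_normal()
        drift = _smooth_curve(rng, cfg.n_channels, cfg.drift_sd, cfg.drift_smoothness)
        plasma = gain * pure + drift + pair_noise_sd * rng.standard_normal(cfg.n_channels)
        serum = (gain * (cfg.specimen_attenuation * pure + offset) + drift
                 + pair_noise_sd * rng.standard_normal(cfg.n_channels))
        p_rows.append(plasma)
        s_rows.append(serum)
        subjects.append(f"{subject_prefix}{j:04d}")
    plasma_set = _as_set(axis, p_rows, subjects, subjects, [0] * n_pairs,
                         specimen="plasma")
    serum_set = _as_set(axis, s_rows, subjects, subjects, [0] * n_pairs,
                        specimen="serum")
    return plasma_set, serum_set


def scenario_config(**overrides) -> PopulationConfig:
    """The frozen default identification scenario, with keyword overrides."""
    return replace(PopulationConfig(), **overrides)


def cross_specimen_config(**overrides) -> PopulationConfig:
    """The frozen plasma-to-serum transfer scenario, with keyword overrides."""
    base = dict(specimen_offset=default_specimen_offset(), specimen_attenuation=0.97)
    base.update(overrides)
    return replace(PopulationConfig(), **base)


def case_control_config(**overrides) -> PopulationConfig:
    """The frozen case-control scenario, with keyword overrides."""
    base = dict(case_effect=default_case_effect())
    base.update(overrides)
    return replace(PopulationConfig(), **base)
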