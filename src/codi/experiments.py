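"""Experiment protocols: augmentation vs. experimental-only training, scans, transfer.

Each ``run_*`` function evaluates a set of training conditions on one frozen
test set, records a hash of that test set so conditions are provably
comparable, and returns an :class:`ExperimentReport`. Randomness is governed
by a single ``rng_seed`` per run; condition-level seeds are derived from it
through a seed sequence, so a report can be reproduced bit-identically from
its config snapshot.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass, field

import numpy as np

from .classify import EvalResult, evaluate, fit_binary, fit_identifier, fit_log_trend
from .core import (
    SimulationConfig,
    VariabilitySource,
    differences_mean_centered,
    differences_paired,
    differences_within_subject,
    generate_cohort,
)
from .errors import LeakageError, ParameterError, ProtocolError
from .spectra_io import SpectraSet
from .synth import ScenarioDataset

__all__ = [
    "ExperimentReport", "default_sources",
    "run_identification", "run_source_ablation", "run_population_scan",
    "run_multibaseline", "run_variance_scan", "run_augmentation_baselines",
    "run_cross_specimen", "run_case_control",
]


@dataclass
class ExperimentReport:
    """Labelled per-condition evaluations on one shared test set."""

    name: str
    conditions: list = field(default_factory=list)  # [(label, EvalResult)]
    seeds_used: list = field(default_factory=list)
    config_snapshot: dict = field(default_factory=dict)
    runtime: float = 0.0
    test_hash: str = ""
    extras: dict = field(default_factory=dict)

    def result(self, label: str) -> EvalResult:
        for lab, res in self.conditions:
            if lab == label:
                return res
        raise KeyError(label)

    def accuracy(self, label: str) -> float:
        return self.result(label).accuracy

    def to_dict(self) -> dict:
        rows = []
        for lab, res in self.conditions:
            rows.append({"condition": lab, "accuracy": res.accuracy,
                         "auc": res.auc, "n_test": res.n_test})
        return {
            "name": self.name, "conditions": rows,
            "seeds_used": [int(s) for s in self.seeds_used],
            "config_snapshot": self.config_snapshot,
            "runtime": self.runtime, "test_hash": self.test_hash,
            "extras": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in self.extras.items()},
        }


def _hash_set(s: SpectraSet) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(s.data).tobytes())
    h.update("|".join(s.labels.tolist()).encode())
    return h.hexdigest()[:16]


def _child_seeds(rng_seed: int, k: int) -> list[int]:
    state = np.random.SeedSequence(rng_seed).generate_state(k, dtype=np.uint32)
    return [int(x) % (2**31) for x in state]


def _snapshot(scenario: ScenarioDataset | None, **kwargs) -> dict:
    snap = dict(kwargs)
    if scenario is not None and scenario.config is not None:
        cfg = dataclasses.asdict(scenario.config)
        for key, val in list(cfg.items()):
            if isinstance(val, dict):  # BandModel fields
                cfg[key] = {k: np.asarray(v).tolist() for k, v in val.items()}
            elif isinstance(val, np.ndarray):
                cfg[key] = val.tolist()
        snap["scenario_config"] = cfg
    return snap


def _check_leakage(scenario: ScenarioDataset) -> None:
    study = set(scenario.train.subjects()) | set(scenario.test.subjects())
    calib = set(scenario.calib_longitudinal.subjects())
    if scenario.calib_specimen_pairs is not None:
        calib |= set(scenario.calib_specimen_pairs[0].subjects())
    if study & calib:
        raise LeakageError(
            f"calibration subjects overlap study subjects: {sorted(study & calib)}"
        )


def default_sources(scenario: ScenarioDataset, scale: float = 1.0) -> list[VariabilitySource]:
    """The scenario's four calibration-derived variability sources.

    1. within-person biological change over time (per-subject mean-centered
       longitudinal deviations of held-out subjects),
    2. clinical-study / collection-protocol variability (mean-centered
       per-study mean spectra of the same held-out longitudinal set; the
       study a measurement belongs to is recorded in its ``batch`` field),
    3. instrument-state and handling drift (mean-centered QC measurements
       spanning both instrument states),
    4. pure device noise (mean-centered blank replicates).
    """
    _check_leakage(scenario)
    lon = scenario.calib_longitudinal
    within = differences_within_subject(lon, "within_person")
    studies = np.array([b.split(":")[0] for b in lon.meta["batch"].to_numpy()])
    study_means = [lon.data[studies == g].mean(axis=0) for g in np.unique(studies)]
    means_set = SpectraSet(lon.axis, np.vstack(study_means),
                           np.array([str(g) for g in np.unique(studies)]))
    study = differences_mean_centered(means_set, "study")
    qc = differences_mean_centered(scenario.calib_qc, "qc_drift")
    rep = differences_mean_centered(scenario.calib_replicates, "replicate_noise")
    return [VariabilitySource(d, scale) for d in (within, study, qc, rep)]


def _codi_cohort(train: SpectraSet, sources, n_per_seed: int, rng_seed: int) -> SpectraSet:
    return generate_cohort(SimulationConfig(seeds=train, sources=list(sources),
                                            n_per_seed=n_per_seed, rng_seed=rng_seed))


def _report(name, scenario, conditions, seeds, t0, test, extras=None, **snap_kwargs):
    return ExperimentReport(
        name=name, conditions=conditions, seeds_used=seeds,
        config_snapshot=_snapshot(scenario, **snap_kwargs),
        runtime=time.perf_counter() - t0, test_hash=_hash_set(test),
        extras=extras or {},
    )


def run_identification(scenario: ScenarioDataset, n_per_seed: int = 1000,
                       sources=None, rng_seed: int = 0) -> ExperimentReport:
    """Single-baseline identification: experimental-only vs. augmented training.

    The training pool must hold exactly one baseline measurement per
    individual; both conditions are evaluated on the identical follow-up
    test set measured under the shifted instrument state.
    """
    t0 = time.perf_counter()
    _, counts = np.unique(scenario.train.labels, return_counts=True)
    if np.any(counts > 1):
        raise ProtocolError("more than one baseline per individual; use run_multibaseline")
    if sources is None:
        sources = default_sources(scenario)
    seeds = _child_seeds(rng_seed, 1)
    exp_model = fit_identifier(scenario.train, "auto")
    cohort = _codi_cohort(scenario.train, sources, n_per_seed, seeds[0])
    codi_model = fit_identifier(cohort, "auto")
    conditions = [
        ("experimental", evaluate(exp_model, scenario.test)),
        ("codi", evaluate(codi_model, scenario.test)),
    ]
    return _report("identification", scenario, conditions, seeds, t0, scenario.test,
                   n_per_seed=n_per_seed, rng_seed=rng_seed)


def run_source_ablation(scenario: ScenarioDataset, n_per_seed: int = 1000,
                        sources=None, rng_seed: int = 0) -> ExperimentReport:
    """Leave-one-source-out ablation of the augmented identification protocol."""
    t0 = time.perf_counter()
    if sources is None:
        sources = default_sources(scenario)
    if len(sources) < 2:
        raise ProtocolError("ablation needs >= 2 sources")
    seeds = _child_seeds(rng_seed, 1 + len(sources))
    conditions = []
    cohort = _codi_cohort(scenario.train, sources, n_per_seed, seeds[0])
    conditions.append(("full", evaluate(fit_identifier(cohort, "auto"), scenario.test)))
    for i, src in enumerate(sources):
        rest = [s for j, s in enumerate(sources) if j != i]
        cohort = _codi_cohort(scenario.train, rest, n_per_seed, seeds[1 + i])
        label = f"without_{src.diffset.source_name or i}"
        conditions.append((label, evaluate(fit_identifier(cohort, "auto"), scenario.test)))
    return _report("source_ablation", scenario, conditions, seeds, t0, scenario.test,
                   n_per_seed=n_per_seed, rng_seed=rng_seed)


def run_population_scan(scenario: ScenarioDataset, sizes, repeats: int = 3,
                        n_per_seed: int = 200, rng_seed: int = 0) -> ExperimentReport:
    """Augmented identification accuracy vs. population size, plus the log-trend fit.

    For each size, ``repeats`` random subject subsets are drawn; the mean
    accuracy per size is regressed on log2(size).
    """
    t0 = time.perf_counter()
    subjects = np.unique(scenario.train.labels)
    sizes = [int(s) for s in sizes]
    if any(s < 2 for s in sizes):
        raise ParameterError("identification needs population sizes >= 2")
    if max(sizes) > subjects.size:
        raise ParameterError(f"size {max(sizes)} exceeds population {subjects.size}")
    if repeats < 1:
        raise ParameterError("repeats must be >= 1")
    sources = default_sources(scenario)
    seeds = _child_seeds(rng_seed, len(sizes) * repeats + 1)
    picker = np.random.default_rng(seeds[-1])
    conditions, mean_acc = [], []
    k = 0
    for size in sizes:
        accs = []
        for r in range(repeats):
            chosen = picker.choice(subjects, size=size, replace=False)
            tr = scenario.train.select(np.isin(scenario.train.labels, chosen))
            te = scenario.test.select(np.isin(scenario.test.labels, chosen))
            cohort = _codi_cohort(tr, sources, n_per_seed, seeds[k]); k += 1
            res = evaluate(fit_identifier(cohort, "auto"), te)
            conditions.append((f"N={size}|rep={r}", res))
            accs.append(res.accuracy)
        mean_acc.append(float(np.mean(accs)))
    slope, intercept, r2 = fit_log_trend(sizes, mean_acc)
    extras = {"sizes": sizes, "mean_accuracy": mean_acc,
              "slope": slope, "intercept": intercept, "r_squared": r2}
    return _report("population_scan", scenario, conditions, seeds, t0, scenario.test,
                   extras=extras, sizes=sizes, repeats=repeats,
                   n_per_seed=n_per_seed, rng_seed=rng_seed)


def run_multibaseline(scenario: ScenarioDataset, max_baselines: int = 6,
                      n_per_seed: int = 1000, rng_seed: int = 0) -> ExperimentReport:
    """Identification vs. number of baseline visits modeled per individual.

    For b = 1..max_baselines, both an experimental-only and an augmented
    classifier are trained on each individual's first b baseline visits and
    evaluated on the fixed post-baseline test set. ``extras`` records the
    augmented-minus-experimental accuracy difference per b.
    """
    t0 = time.perf_counter()
    visits = scenario.train.meta["visit"].astype(int).to_numpy()
    if visits.max() + 1 < max_baselines:
        raise ProtocolError(
            f"scenario provides {visits.max() + 1} baseline visits, need {max_baselines}"
        )
    sources = default_sources(scenario)
    seeds = _child_seeds(rng_seed, max_baselines)
    conditions, diffs = [], []
    for b in range(1, max_baselines + 1):
        tr = scenario.train.select(visits < b)
        exp_res = evaluate(fit_identifier(tr, "auto"), scenario.test)
        cohort = _codi_cohort(tr, sources, n_per_seed, seeds[b - 1])
        codi_res = evaluate(fit_identifier(cohort, "auto"), scenario.test)
        conditions.append((f"experimental|b={b}", exp_res))
        conditions.append((f"codi|b={b}", codi_res))
        diffs.append(codi_res.accuracy - exp_res.accuracy)
    extras = {"baselines": list(range(1, max_baselines + 1)),
              "codi_minus_experimental": diffs}
    return _report("multibaseline", scenario, conditions, seeds, t0, scenario.test,
                   extras=extras, max_baselines=max_baselines,
                   n_per_seed=n_per_seed, rng_seed=rng_seed)


def run_variance_scan(scenario: ScenarioDataset, lambdas, n_per_seed_list,
                      rng_seed: int = 0) -> ExperimentReport:
    """Grid of (variance multiplier, cohort size): excess variance stress test."""
    t0 = time.perf_counter()
    lambdas = [float(l) for l in lambdas]
    ns = [int(n) for n in n_per_seed_list]
    if not lambdas or not ns:
        raise ParameterError("lambdas and n_per_seed_list must be non-empty")
    if any(l < 0 for l in lambdas):
        raise ParameterError("variance multipliers must be >= 0")
    base_sources = default_sources(scenario)
    seeds = _child_seeds(rng_seed, len(lambdas) * len(ns))
    conditions, k = [], 0
    for lam in lambdas:
        sources = [s.with_scale(s.scale * lam) for s in base_sources]
        for n in ns:
            cohort = _codi_cohort(scenario.train, sources, n, seeds[k]); k += 1
            res = evaluate(fit_identifier(cohort, "auto"), scenario.test)
            conditions.append((f"lambda={lam}|n={n}", res))
    return _report("variance_scan", scenario, conditions, seeds, t0, scenario.test,
                   lambdas=lambdas, n_per_seed_list=ns, rng_seed=rng_seed)


def _augment(train: SpectraSet, kind: str, n_per_seed: int, rng_seed: int,
             total_trace: float) -> SpectraSet:
    """Domain-agnostic augmentations, variance-matched to the injected trace."""
    rng = np.random.default_rng(rng_seed)
    n, p = train.data.shape
    X = np.repeat(train.data, n_per_seed, axis=0)
    N = X.shape[0]
    if kind == "additive":
        X = X + np.sqrt(total_trace / p) * rng.standard_normal((N, p))
    elif kind == "multiplicative":
        mean_sq = float((train.data**2).sum(axis=1).mean())
        sd = np.sqrt(total_trace / max(mean_sq, 1e-12))
        X = X * (1.0 + sd * rng.standard_normal(N))[:, None]
    elif kind == "offset_slope":
        t = np.linspace(-1.0, 1.0, p)
        a_sd = np.sqrt(total_trace / (2.0 * p))
        b_sd = np.sqrt(total_trace / (2.0 * float(t @ t)))
        X = (X + a_sd * rng.standard_normal(N)[:, None]
             + np.outer(b_sd * rng.standard_normal(N), t))
    elif kind == "interpolation":
        labels = np.repeat(train.labels, n_per_seed)
        for c in np.unique(labels):
            rows = np.flatnonzero(train.labels == c)
            here = np.flatnonzero(labels == c)
            partners = rng.choice(rows, size=here.size)
            beta = rng.uniform(size=here.size)[:, None]
            X[here] = beta * X[here] + (1.0 - beta) * train.data[partners]
    else:
        raise ParameterError(f"unknown augmentation {kind!r}")
    labels = np.repeat(train.labels, n_per_seed)
    meta = train.meta.loc[train.meta.index.repeat(n_per_seed)].reset_index(drop=True)
    meta["provenance"] = "simulated"
    return SpectraSet(train.axis, X, labels, meta)


AUGMENTATION_KINDS = ("additive", "multiplicative", "offset_slope", "interpolation")


def run_augmentation_baselines(scenario: ScenarioDataset, n_per_seed: int = 1000,
                               rng_seed: int = 0) -> ExperimentReport:
    """Calibration-informed augmentation vs. domain-agnostic schemes.

    The generic schemes (additive white noise, multiplicative gain, baseline
    offset+slope, within-class convex interpolation) are matched to the same
    total injected variance (trace of the injected covariance) for a fair
    comparison, and all conditions share the test set.
    """
    t0 = time.perf_counter()
    sources = default_sources(scenario)
    total_trace = float(sum((s.injected_std() ** 2).sum() for s in sources))
    seeds = _child_seeds(rng_seed, 1 + len(AUGMENTATION_KINDS))
    conditions = [("experimental", evaluate(fit_identifier(scenario.train, "auto"),
                                            scenario.test))]
    cohort = _codi_cohort(scenario.train, sources, n_per_seed, seeds[0])
    conditions.append(("codi", evaluate(fit_identifier(cohort, "auto"), scenario.test)))
    for i, kind in enumerate(AUGMENTATION_KINDS):
        aug = _augment(scenario.train, kind, n_per_seed, seeds[1 + i], total_trace)
        conditions.append((kind, evaluate(fit_identifier(aug, "auto"), scenario.test)))
    return _report("augmentation_baselines", scenario, conditions, seeds, t0,
                   scenario.test, extras={"total_trace": total_trace},
                   n_per_seed=n_per_seed, rng_seed=rng_seed)


def run_cross_specimen(scenario: ScenarioDataset, n_per_seed: int = 1000,
                       shift_mode: str = "uniform", rng_seed: int = 0) -> ExperimentReport:
    """Plasma-to-serum transfer: reference, transfer gap, and mixture recovery.

    Specimen differences are characterized only from held-out pairing
    subjects (serum minus plasma of the same sample); the mixture condition
    adds that paired source, with a mean shift toward serum, to the standard
    augmentation sources.
    """
    t0 = time.perf_counter()
    if scenario.calib_specimen_pairs is None or scenario.test_serum is None:
        raise ProtocolError("scenario lacks specimen pairs or a serum-like test set")
    plasma_cal, serum_cal = scenario.calib_specimen_pairs
    overlap = set(plasma_cal.subjects()) & set(scenario.test_serum.subjects())
    if overlap:
        raise LeakageError(f"pairing subjects overlap test subjects: {sorted(overlap)}")
    sources = default_sources(scenario)
    specimen = VariabilitySource(
        differences_paired(serum_cal, plasma_cal, "specimen"),
        scale=1.0, shift_mode=shift_mode,
    )
    seeds = _child_seeds(rng_seed, 2)
    plasma_cohort = _codi_cohort(scenario.train, sources, n_per_seed, seeds[0])
    plasma_model = fit_identifier(plasma_cohort, "auto")
    mixture_cohort = _codi_cohort(scenario.train, sources + [specimen],
                                  n_per_seed, seeds[1])
    mixture_model = fit_identifier(mixture_cohort, "auto")
    ref = evaluate(plasma_model, scenario.test)
    gap = evaluate(plasma_model, scenario.test_serum)
    rec = evaluate(mixture_model, scenario.test_serum)
    conditions = [("plasma_on_plasma", ref), ("plasma_on_serum", gap),
                  ("mixture_on_serum", rec)]
    drop = ref.accuracy - gap.accuracy
    recovery = (rec.accuracy - gap.accuracy) / drop if drop > 0 else float("nan")
    extras = {"transfer_drop": drop, "recovery_fraction": recovery}
    return _report("cross_specimen", scenario, conditions, seeds, t0, scenario.test_serum,
                   extras=extras, n_per_seed=n_per_seed, shift_mode=shift_mode,
                   rng_seed=rng_seed)


def run_case_control(scenario: ScenarioDataset, n_per_seed: int = 100,
                     training_sizes=(25, 50, 100, 200), repeats: int = 5,
                     rng_seed: int = 0) -> ExperimentReport:
    """Binary case-control AUC vs. experimental training-set size.

    For each size, stratified subsamples of the training pool are drawn;
    experimental-only and augmented ridge-logistic classifiers are evaluated
    by AUC on the fixed held-out test set measured under the shifted state.
    ``extras`` records mean AUC per size and mode.
    """
    t0 = time.perf_counter()
    sizes = [int(s) for s in training_sizes]
    labels = scenario.train.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ProtocolError("case-control scenario needs exactly 2 classes")
    if max(sizes) > scenario.train.n:
        raise ParameterError(f"training size {max(sizes)} exceeds pool {scenario.train.n}")
    sources = default_sources(scenario)
    seeds = _child_seeds(rng_seed, len(sizes) * repeats + 1)
    picker = np.random.default_rng(seeds[-1])
    conditions, k = [], 0
    mean_auc = {"experimental": [], "codi": []}
    for size in sizes:
        aucs = {"experimental": [], "codi": []}
        for r in range(repeats):
            idx = []
            for c in classes:
                rows = np.flatnonzero(labels == c)
                take = max(int(round(size * (rows.size / labels.size))), 2)
                idx.append(picker.choice(rows, size=min(take, rows.size), replace=False))
            sub = scenario.train.select(np.sort(np.concatenate(idx)))
            exp_res = evaluate(fit_binary(sub), scenario.test)
            cohort = _codi_cohort(sub, sources, n_per_seed, seeds[k]); k += 1
            codi_res = evaluate(fit_binary(cohort), scenario.test)
            conditions.append((f"experimental|n={size}|rep={r}", exp_res))
            conditions.append((f"codi|n={size}|rep={r}", codi_res))
            aucs["experimental"].append(exp_res.auc)
            aucs["codi"].append(codi_res.auc)
        for mode in mean_auc:
            mean_auc[mode].append(float(np.mean(aucs[mode])))
    extras = {"training_sizes": sizes,
              "mean_auc_experimental": mean_auc["experimental"],
              "mean_auc_codi": mean_auc["codi"]}
    return _report("case_control", scenario, conditions, seeds, t0, scenario.test,
                   extras=extras, n_per_seed=n_per_seed, training_sizes=sizes,
                   repeats=repeats, rng_seed=rng_seed)
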