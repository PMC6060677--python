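"""Synthetic 1D 1H NMR urine spectra with recorded ground truth.

The generator renders each metabolite as a set of Lorentzian multiplets on a
shared ppm grid and then layers on the nuisance structure that the
preprocessing chain is meant to undo:

* per-sample multiplicative dilution (log-normal), as urine concentration
  varies strongly between voids — the target of probabilistic quotient
  normalization;
* per-sample, per-metabolite chemical-shift jitter (Gaussian, in ppm),
  mimicking pH/ionic-strength dependent position drift — the target of
  recursive segment peak alignment;
* a smooth low-order baseline, additive Gaussian noise, and optionally a
  residual solvent hump in the 4.7-4.9 ppm water region.

Class structure enters through an ``effect_map`` of fold-changes applied to
the mean concentration of designated metabolites, around which individual
samples vary with ~25% biological CV (log-normal).  Everything drawn is
recorded in a :class:`GroundTruth` so downstream stages can be tested as
parameter-recovery problems.

Multiplet line positions are nominal textbook values for common urinary
metabolites; they are configurable defaults, not measurements, and no test
should assert an absolute ppm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectra_io import SampleTable, SpectraMatrix

__all__ = [
    "Multiplet",
    "MetabolitePattern",
    "PeakLibrary",
    "CohortDesign",
    "GroundTruth",
    "make_peak_library",
    "simulate_spectrum",
    "simulate_cohort",
]


@dataclass(frozen=True)
class Multiplet:
    """One multiplet: ``n_lines`` Lorentzians split by ``j_spacing_ppm``.

    Line intensities follow the binomial (Pascal) pattern of first-order
    coupling; ``relative_intensity`` scales the whole multiplet and
    ``width_ppm`` is the full width at half maximum of each line.
    """

    center_ppm: float
    relative_intensity: float
    n_lines: int = 1
    j_spacing_ppm: float = 0.0
    width_ppm: float = 0.003

    def __post_init__(self) -> None:
        if self.relative_intensity < 0:
            raise ValueError("relative_intensity must be >= 0")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.j_spacing_ppm < 0:
            raise ValueError("j_spacing_ppm must be >= 0")
        if self.width_ppm <= 0:
            raise ValueError("width_ppm must be > 0")


@dataclass(frozen=True)
class MetabolitePattern:
    name: str
    multiplets: tuple[Multiplet, ...]

    @property
    def apex_ppm(self) -> float:
        """Position of the strongest individual line.

        The most intense multiplet wins (first on ties); within it, the line
        with the largest binomial weight (the lower-offset one when the line
        count is even — a doublet has no line at its centre).
        """
        best = max(self.multiplets, key=lambda m: m.relative_intensity)
        k = (best.n_lines - 1) // 2
        return best.center_ppm + (k - (best.n_lines - 1) / 2.0) * best.j_spacing_ppm


@dataclass
class PeakLibrary:
    """Named collection of metabolite multiplet patterns."""

    entries: list[MetabolitePattern]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("metabolite names must be unique")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __getitem__(self, name: str) -> MetabolitePattern:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(f"unknown metabolite: {name!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def apex_ppm(self) -> dict[str, float]:
        return {e.name: e.apex_ppm for e in self.entries}


# (center_ppm, relative_intensity, n_lines, j_spacing_ppm, width_ppm)
# Nominal positions from public 1H NMR reference data for urine at pH ~7;
# j spacings of ~8 Hz expressed in ppm at 600 MHz (0.013 ppm).
_J = 0.013
_DEFAULT_PATTERNS: dict[str, list[tuple[float, float, int, float, float]]] = {
    "hippurate": [
        (7.83, 2.0, 2, _J, 0.003),
        (7.64, 1.0, 3, _J, 0.003),
        (7.55, 1.6, 3, _J, 0.003),
        (3.97, 1.6, 2, 0.01, 0.003),
    ],
    "p-cresol sulphate": [
        (7.28, 1.2, 2, _J, 0.003),
        (7.21, 1.2, 2, _J, 0.003),
        (2.35, 1.8, 1, 0.0, 0.003),
    ],
    "p-cresol glucuronide": [
        (7.23, 0.8, 2, _J, 0.003),
        (7.05, 0.8, 2, _J, 0.003),
        (2.29, 1.2, 1, 0.0, 0.003),
    ],
    "tyrosine": [
        (7.19, 1.0, 2, _J, 0.003),
        (6.89, 1.0, 2, _J, 0.003),
        (3.05, 0.5, 2, 0.012, 0.003),
    ],
    "3-HPPA": [
        (6.83, 0.6, 2, _J, 0.003),
        (2.83, 0.8, 3, 0.012, 0.003),
        (2.46, 0.8, 3, 0.012, 0.003),
    ],
    "N-methylnicotinamide": [
        (9.27, 1.2, 1, 0.0, 0.003),
        (8.96, 0.8, 2, _J, 0.003),
        (8.90, 0.8, 2, _J, 0.003),
        (4.47, 1.0, 1, 0.0, 0.003),
    ],
    "formate": [(8.45, 1.0, 1, 0.0, 0.003)],
    "creatine": [(3.03, 1.5, 1, 0.0, 0.003), (3.93, 1.0, 1, 0.0, 0.003)],
    "creatinine": [(3.05, 2.0, 1, 0.0, 0.003), (4.06, 1.3, 1, 0.0, 0.003)],
    "taurine": [(3.42, 1.0, 3, 0.011, 0.003), (3.25, 1.0, 3, 0.011, 0.003)],
    "trimethylamine": [(2.87, 1.5, 1, 0.0, 0.003)],
    "phenylacetylglycine": [
        (7.41, 0.8, 2, _J, 0.003),
        (7.36, 0.6, 3, _J, 0.003),
        (3.68, 1.0, 1, 0.0, 0.003),
    ],
    "bile acids": [(0.72, 1.0, 1, 0.0, 0.006)],
    "citrate": [(2.66, 1.0, 2, 0.026, 0.003), (2.54, 1.0, 2, 0.026, 0.003)],
    "lactate": [(1.33, 1.2, 2, 0.011, 0.003), (4.12, 0.4, 4, 0.011, 0.003)],
}

#: Multiplet fields an override may touch.
_OVERRIDABLE = ("relative_intensity", "width_ppm")


def make_peak_library(overrides: dict[str, dict[str, float]] | None = None) -> PeakLibrary:
    """Build the default urinary metabolite library, optionally overridden.

    ``overrides`` maps metabolite name to ``{field: value}`` where field is
    one of ``relative_intensity`` (applied as the new value to every
    multiplet of that metabolite; 0 silences it) or ``width_ppm``.
    Deterministic: identical arguments give identical libraries.
    """
    overrides = overrides or {}
    unknown = sorted(set(overrides) - set(_DEFAULT_PATTERNS))
    if unknown:
        raise KeyError(f"unknown metabolite(s) in overrides: {unknown}")
    entries = []
    for name, mults in _DEFAULT_PATTERNS.items():
        ov = overrides.get(name, {})
        bad = sorted(set(ov) - set(_OVERRIDABLE))
        if bad:
            raise KeyError(f"unknown override field(s) for {name!r}: {bad}")
        built = []
        for center, rel, n_lines, j, width in mults:
            rel = float(ov.get("relative_intensity", rel))
            width = float(ov.get("width_ppm", width))
            built.append(Multiplet(center, rel, n_lines, j, width))
        entries.append(MetabolitePattern(name, tuple(built)))
    return PeakLibrary(entries)


def _binomial_weights(n: int) -> np.ndarray:
    w = np.array([math.comb(n - 1, k) for k in range(n)], dtype=float)
    return w / w.sum()


def _lorentzian(axis: np.ndarray, center: float, height: float, width: float) -> np.ndarray:
    hw = 0.5 * width
    return height * hw**2 / ((axis - center) ** 2 + hw**2)


def simulate_spectrum(
    library: PeakLibrary,
    concentrations: dict[str, float],
    axis: np.ndarray,
    jitter: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    baseline_amplitude: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one spectrum on ``axis`` (strictly monotone ppm grid).

    Each multiplet contributes ``n_lines`` Lorentzians centred at
    ``center_ppm + jitter`` offset by multiples of ``j_spacing_ppm`` and
    scaled by ``concentration * relative_intensity`` times the binomial line
    weight.  A smooth cubic baseline and i.i.d. Gaussian noise are added when
    requested (both need ``rng``).  Lines whose jitter pushes them off the
    axis are silently truncated by the grid.
    """
    axis = np.asarray(axis, dtype=float)
    d = np.diff(axis)
    if axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("axis must be strictly monotone")
    jitter = jitter or {}
    out = np.zeros_like(axis)
    for name, conc in concentrations.items():
        conc = float(conc)
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
        if conc == 0.0:
            continue
        pattern = library[name]
        off = float(jitter.get(name, 0.0))
        for m in pattern.multiplets:
            if m.relative_intensity == 0.0:
                continue
            weights = _binomial_weights(m.n_lines)
            for k, wt in enumerate(weights):
                pos = m.center_ppm + off + (k - (m.n_lines - 1) / 2.0) * m.j_spacing_ppm
                out += _lorentzian(axis, pos, conc * m.relative_intensity * wt, m.width_ppm)
    if baseline_amplitude > 0.0:
        if rng is None:
            raise ValueError("rng required when baseline_amplitude > 0")
        u = np.linspace(-1.0, 1.0, axis.size)
        coefs = rng.uniform(-1.0, 1.0, size=4)
        out += baseline_amplitude * 0.5 * (coefs[0] + coefs[1] * u + coefs[2] * u**2 + coefs[3] * u**3)
    if noise_sd > 0.0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        out += rng.normal(0.0, noise_sd, size=axis.size)
    return out


@dataclass
class CohortDesign:
    """Design of a simulated cohort: sizes, grid, effects and nuisance levels.

    ``effect_map`` maps class label -> {metabolite: fold-change} applied to
    the class mean concentration (reference level 1.0); fold-changes must be
    positive.  Biological concentration variation is log-normal with two
    parts: shared physiological variation carried by ``n_bg_factors`` latent
    axes (named metabolites load on them with per-factor scale
    ``met_factor_sigma``) and compound-unique variation of log-scale SD
    ``conc_sigma``; with the defaults the total per-metabolite CV is ~25%.
    ``dilution_sigma`` is the log-scale SD of the per-sample dilution
    factor.  ``jitter_sd_ppm`` is the SD of per-sample, per-metabolite
    position jitter.

    ``n_background`` minor unassigned compounds (random singlet positions and
    scales drawn once per cohort) and ``n_envelope`` broad macromolecular
    envelope components (Gaussian humps ~1 ppm wide spread across the range)
    emulate the crowded urinary matrix: real urine spectra carry correlated
    biological variance almost everywhere, so after unit-variance scaling
    the spectrum is not dominated by amplified instrument noise.  Background
    compounds are co-regulated through ``n_bg_factors`` latent biological
    axes (diet, microbiome, renal function ...): per sample, each compound's
    log-concentration is its loading vector (entries ~ N(0, bg_factor_sigma))
    times the sample's factor scores plus unique N(0, bg_unique_sigma)
    variation — matching the observation that most urinary spectral variance
    concentrates in a few components.  Background positions avoid the named
    metabolites' line centres (the named panel is reportable precisely
    because its lines are resolvable).  The default grid spacing
    (9 ppm / 9000 points = 0.001 ppm) resolves the default 0.003 ppm
    linewidth with ~3 points so that sub-grid line placement does not alias
    peak heights.
    """

    n_per_class: dict[str, int]
    ppm_range: tuple[float, float] = (0.5, 9.5)
    n_points: int = 9000
    effect_map: dict[str, dict[str, float]] = field(default_factory=dict)
    dilution_sigma: float = 0.4
    jitter_sd_ppm: float = 0.002
    noise_sd: float = 0.003
    baseline_amplitude: float = 0.05
    conc_sigma: float = 0.15
    met_factor_sigma: float = 0.08
    n_background: int = 150
    background_amplitude: float = 0.3
    n_bg_factors: int = 6
    bg_factor_sigma: float = 0.2
    bg_unique_sigma: float = 0.1
    n_envelope: int = 8
    envelope_amplitude: float = 0.15
    water_residual: bool = True
    batch: str = "2009"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_class:
            raise ValueError("n_per_class must not be empty")
        for cls, n in self.n_per_class.items():
            if n < 1:
                raise ValueError(f"class {cls!r} is empty")
        lo, hi = self.ppm_range
        if not lo < hi:
            raise ValueError("ppm_range low must be < high")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        for cls, effects in self.effect_map.items():
            for met, fold in effects.items():
                if fold <= 0:
                    raise ValueError(f"fold-change for ({cls!r}, {met!r}) must be > 0")
        for name in (
            "dilution_sigma",
            "jitter_sd_ppm",
            "noise_sd",
            "baseline_amplitude",
            "conc_sigma",
            "met_factor_sigma",
            "n_background",
            "background_amplitude",
            "n_envelope",
            "envelope_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Everything the simulator drew, keyed for parameter-recovery tests."""

    dilution_factors: dict[str, float]
    jitter: dict[str, dict[str, float]]
    effect_metabolites: dict[str, list[tuple[str, float]]]
    apex_ppm: dict[str, float]
    seed: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "dilution_factors": self.dilution_factors,
            "jitter": self.jitter,
            "effect_metabolites": {
                cls: [[m, f] for m, f in pairs]
                for cls, pairs in self.effect_metabolites.items()
            },
            "apex_ppm": self.apex_ppm,
            "seed": self.seed,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            dilution_factors=d["dilution_factors"],
            jitter=d["jitter"],
            effect_metabolites={
                c: [(m, f) for m, f in pairs] for c, pairs in d["effect_metabolites"].items()
            },
            apex_ppm=d["apex_ppm"],
            seed=d["seed"],
        )


# Geometric-mean urinary AL scale per class, echoing the case > household >
# village ordering of exposure; arbitrary units.
_AL_SCALE = {
    "case": 2.5,
    "household_control": 1.7,
    "post_dose": 2.5,
    "al_ddt": 2.5,
    "al_only": 2.0,
}


def simulate_cohort(
    design: CohortDesign, library: PeakLibrary | None = None
) -> tuple[SpectraMatrix, SampleTable, GroundTruth]:
    """Simulate one spectrum per sample plus metadata and ground truth.

    The RNG is a single ``default_rng(design.seed)`` stream.  Draw order:
    the cohort-level structure — named-metabolite factor loadings,
    background compounds (positions, scales, factor loadings), envelope
    widths and scales; then per sample: the latent factor scores, per-
    metabolite unique log-variation (library order), per-metabolite jitter,
    background unique log-variation, background jitter, envelope
    concentrations, the dilution factor, the water-residual amplitude (if
    enabled), baseline coefficients, the noise vector, and finally the
    metadata fields (gender, age, AL level).  Samples are generated class by class in ``n_per_class``
    insertion order, so identical designs give bit-identical cohorts.
    """
    library = library or make_peak_library()
    unknown = sorted(
        {m for eff in design.effect_map.values() for m in eff} - set(library.names)
    )
    if unknown:
        raise KeyError(f"effect_map references unknown metabolite(s): {unknown}")
    rng = np.random.default_rng(design.seed)
    lo, hi = design.ppm_range
    axis = np.linspace(hi, lo, design.n_points)  # descending by convention

    nfac = design.n_bg_factors
    n_named = len(library.names)
    named_loadings = (
        design.met_factor_sigma * rng.normal(0.0, 1.0, size=(n_named, nfac))
        if nfac
        else np.zeros((n_named, 0))
    )
    nbg = design.n_background
    if nbg:
        named_lines = np.array(
            [
                mult.center_ppm + (k - (mult.n_lines - 1) / 2.0) * mult.j_spacing_ppm
                for entry in library.entries
                for mult in entry.multiplets
                for k in range(mult.n_lines)
            ]
        )
        bg_centers = np.empty(nbg)
        for b in range(nbg):  # rejection-sample away from named line centres
            for _ in range(200):
                c = float(rng.uniform(lo + 0.05, hi - 0.05))
                if named_lines.size == 0 or np.min(np.abs(named_lines - c)) > 0.015:
                    bg_centers[b] = c
                    break
            else:
                bg_centers[b] = c
        bg_scales = design.background_amplitude * np.exp(rng.normal(0.0, 0.5, size=nbg))
        bg_loadings = (
            design.bg_factor_sigma * rng.normal(0.0, 1.0, size=(nbg, nfac))
            if nfac
            else np.zeros((nbg, 0))
        )
    else:
        bg_centers = bg_scales = np.empty(0)
        bg_loadings = np.zeros((0, nfac))
    nenv = design.n_envelope
    if nenv:
        env_centers = np.linspace(lo + 0.3, hi - 0.3, nenv)
        env_widths = rng.uniform(0.8, 1.6, size=nenv)  # Gaussian sigma, ppm
        env_scales = design.envelope_amplitude * np.exp(rng.normal(0.0, 0.3, size=nenv))
    else:
        env_centers = env_widths = env_scales = np.empty(0)

    ids: list[str] = []
    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    dilution: dict[str, float] = {}
    jitter_rec: dict[str, dict[str, float]] = {}

    for cls, n in design.n_per_class.items():
        effects = design.effect_map.get(cls, {})
        for i in range(n):
            sid = f"{cls}_{i + 1:03d}"
            factors = rng.normal(0.0, 1.0, size=nfac) if nfac else np.empty(0)
            named_shared = named_loadings @ factors if nfac else np.zeros(n_named)
            conc = {}
            for k, name in enumerate(library.names):
                mean = effects.get(name, 1.0)
                conc[name] = mean * float(
                    np.exp(named_shared[k] + rng.normal(0.0, design.conc_sigma))
                )
            jit = {
                name: float(rng.normal(0.0, design.jitter_sd_ppm))
                for name in library.names
            }
            signal = simulate_spectrum(library, conc, axis, jitter=jit)
            if nbg:
                bg_log = bg_loadings @ factors + rng.normal(
                    0.0, design.bg_unique_sigma, size=nbg
                )
                bg_conc = bg_scales * np.exp(bg_log)
                bg_jit = rng.normal(0.0, design.jitter_sd_ppm, size=nbg)
                for center, height, off in zip(bg_centers, bg_conc, bg_jit):
                    signal = signal + _lorentzian(axis, center + off, height, 0.003)
            if nenv:
                env_conc = env_scales * np.exp(rng.normal(0.0, design.conc_sigma, size=nenv))
                for center, height, width in zip(env_centers, env_conc, env_widths):
                    signal = signal + height * np.exp(-0.5 * ((axis - center) / width) ** 2)
            dil = float(np.exp(rng.normal(0.0, design.dilution_sigma)))
            spec = dil * signal
            if design.water_residual:
                amp = 2.0 * float(rng.uniform(0.5, 1.5))
                spec = spec + _lorentzian(axis, 4.8, amp, 0.08)
            spec = spec + simulate_spectrum(
                library,
                {},
                axis,
                noise_sd=design.noise_sd,
                baseline_amplitude=design.baseline_amplitude,
                rng=rng,
            )
            gender = "M" if rng.uniform() < 0.5 else "F"
            age = int(rng.integers(5, 70))
            al = 50.0 * _AL_SCALE.get(cls, 1.0) * float(np.exp(rng.normal(0.0, 0.8)))
            ids.append(sid)
            rows.append(spec)
            dilution[sid] = dil
            jitter_rec[sid] = jit
            meta_rows.append(
                {
                    "id": sid,
                    "class_label": cls,
                    "batch": design.batch,
                    "gender": gender,
                    "age": age,
                    "al_level": al,
                }
            )

    import pandas as pd

    matrix = SpectraMatrix(axis, np.vstack(rows), ids)
    table = SampleTable(pd.DataFrame(meta_rows))
    truth = GroundTruth(
        dilution_factors=dilution,
        jitter=jitter_rec,
        effect_metabolites={
            cls: sorted(eff.items()) for cls, eff in design.effect_map.items()
        },
        apex_ppm=library.apex_ppm(),
        seed=design.seed,
    )
    return matrix, table, truth
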