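"""Measurement-level paired-cohort simulator.

Emulates the statistical structure of a paired dual-scanner study without
any imaging: per subject and outcome parameter, the first-generation
(XCTI) value is drawn from a normal population distribution and the
second-generation (XCTII) value follows a linear inter-scanner
relationship with additive Gaussian noise on the XCTII side (noise sits on
the XCTII side because calibration regresses XCTII on XCTI).

``reference_regimes`` supplies default slope/intercept/R^2 regimes per
site, method and parameter spanning the range observed between the two
HR-pQCT generations (slopes from 0.23 for cortical porosity to 1.77 for
bone volume fraction), together with physiologically plausible XCTI
population means and SDs.  The noise SD needed to hit a target R^2 follows
from the signal-to-noise identity R^2 = s^2 V / (s^2 V + n^2) for slope s,
population variance V and noise variance n^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import PARAMETER_UNITS, OutcomeTable

__all__ = [
    "CohortParameterSpec",
    "CohortSimSpec",
    "generate_paired_cohort",
    "noise_sd_for_r2",
    "reference_regimes",
]


def noise_sd_for_r2(true_slope: float, xcti_sd: float, r2: float) -> float:
    """XCTII-side noise SD that yields population R^2 ``r2`` for the pair."""
    if not 0.0 < r2 <= 1.0:
        raise ValueError("r2 must lie in (0, 1]")
    if r2 == 1.0:
        return 0.0
    return abs(true_slope) * xcti_sd * np.sqrt((1.0 - r2) / r2)


@dataclass
class CohortParameterSpec:
    """Inter-scanner relationship for one outcome parameter."""

    name: str
    true_slope: float
    true_intercept: float
    xcti_mean: float
    xcti_sd: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in PARAMETER_UNITS:
            raise ValueError(f"unknown parameter {self.name!r}")
        if self.xcti_sd <= 0:
            raise ValueError("xcti_sd must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class CohortSimSpec:
    """Cohort size, per-parameter relationships, and the master seed."""

    n_subjects: int
    parameters: list[CohortParameterSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be at least 3")
        if not self.parameters:
            raise ValueError("at least one parameter spec required")


def generate_paired_cohort(
    spec: CohortSimSpec, method: str = "standard"
) -> tuple[OutcomeTable, OutcomeTable]:
    """Simulate a paired cohort; returns (XCTI table, XCTII table).

    Reproducible: the master seed is spawned into independent per-parameter
    streams, so adding a parameter does not perturb the others.
    """
    rng_streams = np.random.default_rng(spec.seed).spawn(len(spec.parameters))
    ids = [f"S{i + 1:03d}" for i in range(spec.n_subjects)]
    rec_i, rec_ii = [], []
    for pspec, rng in zip(spec.parameters, rng_streams):
        x = rng.normal(pspec.xcti_mean, pspec.xcti_sd, size=spec.n_subjects)
        y = pspec.true_slope * x + pspec.true_intercept
        if pspec.noise_sd > 0:
            y = y + rng.normal(0.0, pspec.noise_sd, size=spec.n_subjects)
        units = PARAMETER_UNITS[pspec.name]
        for sid, xi, yi in zip(ids, x, y):
            rec_i.append(dict(subject_id=sid, parameter=pspec.name, scanner="XCTI",
                              method="standard", value=xi, units=units))
            rec_ii.append(dict(subject_id=sid, parameter=pspec.name, scanner="XCTII",
                               method=method, value=yi, units=units))
    return OutcomeTable.from_records(rec_i), OutcomeTable.from_records(rec_ii)


# Default simulation regimes: inter-scanner slope/intercept/R^2 per outcome,
# with XCTI population mean and SD.  Slopes and R^2 span the range seen
# between HR-pQCT generations; means/SDs are plausible adult distal-site
# values on the first-generation scale (densities mgHA/cm^3, areas mm^2,
# lengths mm, Tb.N 1/mm, fractions unitless).
_REGIMES: dict[tuple[str, str], dict[str, tuple[float, float, float, float, float]]] = {
    # (slope, intercept, r2, xcti_mean, xcti_sd)
    ("radius", "standard"): {
        "Tt.BMD": (1.03, -3.07, 0.95, 320.0, 60.0),
        "Tb.Ar": (0.96, 16.51, 0.91, 130.0, 35.0),
        "Tb.BMD": (1.03, -14.20, 0.99, 160.0, 40.0),
        "BV/TV": (1.77, -0.02, 0.97, 0.14, 0.03),
        "Tb.N": (0.77, -0.11, 0.76, 2.0, 0.30),
        "Tb.Th": (1.04, 0.16, 0.69, 0.07, 0.010),
        "Tb.Sp": (1.68, -0.06, 0.88, 0.45, 0.10),
        "Tb.1/N.SD": (1.43, -0.01, 0.92, 0.20, 0.05),
        "Ct.Ar": (0.95, 5.50, 0.97, 55.0, 12.0),
        "Ct.BMD": (1.16, -199.87, 0.88, 880.0, 60.0),
        "Ct.Pm": (1.02, -1.71, 0.96, 70.0, 8.0),
        "Ct.Po": (0.23, 0.00, 0.83, 0.02, 0.010),
        "Ct.Th": (0.99, 0.15, 0.92, 0.75, 0.20),
        "Ct.Po.Dm": (0.63, 0.07, 0.21, 0.15, 0.02),
    },
    ("radius", "LH"): {
        "BV/TV": (1.29, 0.06, 0.97, 0.14, 0.03),
        "Tb.N": (0.74, 0.18, 0.63, 2.0, 0.30),
        "Tb.Th": (0.60, 0.17, 0.66, 0.07, 0.010),
        "Tb.Sp": (1.18, 0.04, 0.79, 0.45, 0.10),
        "Tb.1/N.SD": (1.10, 0.01, 0.95, 0.20, 0.05),
        "Ct.Po": (0.38, 0.01, 0.43, 0.02, 0.010),
        "Ct.Po.Dm": (0.35, 0.12, 0.36, 0.15, 0.02),
    },
    ("tibia", "standard"): {
        "Tt.BMD": (1.00, 0.06, 0.995, 300.0, 55.0),
        "Tb.Ar": (1.02, -4.24, 0.99, 600.0, 120.0),
        "Tb.BMD": (1.04, -14.56, 0.995, 170.0, 40.0),
        "BV/TV": (1.66, 0.01, 0.99, 0.15, 0.03),
        "Tb.N": (0.60, 0.20, 0.82, 2.0, 0.30),
        "Tb.Th": (1.16, 0.16, 0.31, 0.07, 0.010),
        "Tb.Sp": (1.28, 0.14, 0.79, 0.45, 0.10),
        "Tb.1/N.SD": (0.98, 0.08, 0.82, 0.20, 0.05),
        "Ct.Ar": (1.01, 4.08, 0.99, 120.0, 25.0),
        "Ct.BMD": (0.92, 58.42, 0.95, 850.0, 70.0),
        "Ct.Pm": (1.01, -0.77, 0.995, 105.0, 10.0),
        "Ct.Po": (0.47, 0.00, 0.83, 0.06, 0.02),
        "Ct.Th": (1.12, 0.06, 0.99, 1.20, 0.30),
        "Ct.Po.Dm": (1.20, 0.00, 0.38, 0.15, 0.02),
    },
    ("tibia", "LH"): {
        "BV/TV": (1.19, 0.08, 0.97, 0.15, 0.03),
        "Tb.N": (0.59, 0.34, 0.83, 2.0, 0.30),
        "Tb.Th": (0.61, 0.17, 0.48, 0.07, 0.010),
        "Tb.Sp": (1.11, 0.12, 0.83, 0.45, 0.10),
        "Tb.1/N.SD": (0.93, 0.06, 0.87, 0.20, 0.05),
        "Ct.Po": (0.72, 0.02, 0.52, 0.06, 0.02),
        "Ct.Po.Dm": (0.65, 0.08, 0.68, 0.15, 0.02),
    },
}


def reference_regimes(site: str = "tibia", method: str = "standard",
                      parameters: list[str] | None = None) -> list[CohortParameterSpec]:
    """Default per-parameter cohort specs for a site/method regime.

    Noise SDs are derived from each regime's R^2 via :func:`noise_sd_for_r2`.
    """
    try:
        table = _REGIMES[(site, method)]
    except KeyError:
        raise ValueError(
            f"no regime for site={site!r}, method={method!r}; "
            f"available: {sorted(_REGIMES)}"
        ) from None
    names = parameters if parameters is not None else list(table)
    specs = []
    for name in names:
        if name not in table:
            raise ValueError(f"no {site}/{method} regime for parameter {name!r}")
        slope, intercept, r2, mean, sd = table[name]
        specs.append(
            CohortParameterSpec(
                name=name, true_slope=slope, true_intercept=intercept,
                xcti_mean=mean, xcti_sd=sd,
                noise_sd=noise_sd_for_r2(slope, sd, r2),
            )
        )
    return specs
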