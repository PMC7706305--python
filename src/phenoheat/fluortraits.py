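"""Derivation of chlorophyll-fluorescence parameters from raw PAM signals.

A light-curve measurement of a dark-adapted plant yields the minimal and
maximal fluorescence (``F0``, ``Fm``) plus, for each of six increasing
actinic light steps (``Lss1``..``Lss6``), the light-adapted minimal,
steady-state and maximal fluorescence (``F0'``, ``Ft'``, ``Fm'``).  From
these the standard quenching analysis parameters are derived:

========  =======================================  =========================
name      formula                                  meaning
========  =======================================  =========================
Fv        Fm - F0                                  variable fluorescence
QYmax     Fv / Fm                                  max PSII quantum yield
Fv'       Fm' - F0'                                light-adapted variable F
QY'       (Fm' - Ft') / Fm'                        PSII operating efficiency
NPQ       (Fm - Fm') / Fm'                         nonphotochemical quenching
qN        (Fm - Fm') / (Fm - F0')                  NPQ coefficient
qP        (Fm' - Ft') / (Fm' - F0')                photochemical q. coeff.
Fq'       Fm' - Ft'                                photochemical quenching
========  =======================================  =========================

``NPQ`` is referenced to the dark-adapted ``Fm``.  The algebraic identity
``QY' = qP * Fv'/Fm'`` holds exactly and is used as an internal consistency
check downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

N_LIGHT_STEPS = 6

#: Fixed long-format trait vocabulary: dark-adapted signals, per-step
#: light-adapted families, morphology and temperature.
_PER_STEP_FAMILIES = ("F0p", "Ftp", "Fmp", "Fvp", "QYp", "NPQ", "qN", "qP", "Fq")
_MORPHO_TRAITS = (
    "area",
    "perimeter",
    "compactness",
    "roundness",
    "eccentricity",
    "isotropy",
    "RMS",
    "SOL",
)
TRAIT_VOCABULARY: tuple[str, ...] = (
    ("F0", "Fm", "Fv", "QYmax")
    + tuple(
        f"{fam}_Lss{k}" for fam in _PER_STEP_FAMILIES for k in range(1, N_LIGHT_STEPS + 1)
    )
    + _MORPHO_TRAITS
    + ("temperature",)
)


class LightStepSignal(NamedTuple):
    """Raw signals recorded at one actinic light step."""

    f0p: float
    ftp: float
    fmp: float


class LightStepTraits(NamedTuple):
    """Parameters derived from one light step."""

    fvp: float
    qyp: float
    npq: float
    qn: float
    qp: float
    fqp: float


@dataclass(frozen=True)
class RawFluorescence:
    """Raw fluorescence signals of one plant on one measuring day (a.u.)."""

    f0: float
    fm: float
    steps: tuple[LightStepSignal, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "steps", tuple(LightStepSignal(*s) for s in self.steps)
        )


@dataclass(frozen=True)
class DerivedFluor:
    """All derived fluorescence parameters for one plant-day."""

    fv: float
    qymax: float
    steps: tuple[LightStepTraits, ...]


class FluorDomainError(ValueError):
    """Raw signals violate the domain of a derivation formula."""


def validate_raw(raw: RawFluorescence) -> list[str]:
    """Report invariant violations of a raw signal set (never raises).

    Checks positivity of every signal, ``Fm > F0``, and per step
    ``Fm' > Ft'`` and ``Fm' > F0'``.  Returns a list of human-readable
    violation strings; an empty list means the record is valid.
    """
    report: list[str] = []
    if not raw.f0 > 0:
        report.append("F0>0 violated")
    if not raw.fm > 0:
        report.append("Fm>0 violated")
    if not raw.fm > raw.f0:
        report.append("Fm>F0 violated")
    for k, step in enumerate(raw.steps, start=1):
        if not (step.f0p > 0 and step.ftp > 0 and step.fmp > 0):
            report.append(f"positivity violated at Lss{k}")
        if not step.fmp > step.ftp:
            report.append(f"Fmprime>Ftprime violated at Lss{k}")
        if not step.fmp > step.f0p:
            report.append(f"Fmprime>F0prime violated at Lss{k}")
    return report


def derive_dark(f0: float, fm: float) -> tuple[float, float]:
    """Dark-adapted parameters ``(Fv, QYmax)`` from ``F0`` and ``Fm``."""
    if not (f0 > 0 and fm > 0):
        raise FluorDomainError(f"signals must be positive, got F0={f0}, Fm={fm}")
    if not fm > f0:
        raise FluorDomainError(f"Fm must exceed F0, got F0={f0}, Fm={fm}")
    fv = fm - f0
    return fv, fv / fm


def derive_light(
    step: LightStepSignal | tuple[float, float, float], f0: float, fm: float
) -> LightStepTraits:
    """Light-adapted parameters for one actinic step.

    Parameters
    ----------
    step
        ``(F0', Ft', Fm')`` triple for the step.
    f0, fm
        Dark-adapted minimal and maximal fluorescence.
    """
    f0p, ftp, fmp = step
    if not (f0p > 0 and ftp > 0 and fmp > 0 and f0 > 0 and fm > 0):
        raise FluorDomainError("all raw signals must be positive")
    if not fmp > f0p:
        raise FluorDomainError(f"Fm'={fmp} must exceed F0'={f0p}")
    if not fmp > ftp:
        raise FluorDomainError(f"Fm'={fmp} must exceed Ft'={ftp}")
    if not fm > f0p:
        raise FluorDomainError(f"Fm={fm} must exceed F0'={f0p}")
    fvp = fmp - f0p
    fqp = fmp - ftp
    qyp = fqp / fmp
    npq = (fm - fmp) / fmp
    qn = (fm - fmp) / (fm - f0p)
    qp = fqp / fvp
    return LightStepTraits(fvp=fvp, qyp=qyp, npq=npq, qn=qn, qp=qp, fqp=fqp)


def derive_all(raw: RawFluorescence) -> DerivedFluor:
    """Derive the full parameter set for one plant-day record."""
    fv, qymax = derive_dark(raw.f0, raw.fm)
    steps = tuple(derive_light(s, raw.f0, raw.fm) for s in raw.steps)
    return DerivedFluor(fv=fv, qymax=qymax, steps=steps)


def fluor_trait_dict(raw: RawFluorescence) -> dict[str, float]:
    """Flatten raw + derived fluorescence values into the trait vocabulary."""
    der = derive_all(raw)
    out: dict[str, float] = {
        "F0": raw.f0,
        "Fm": raw.fm,
        "Fv": der.fv,
        "QYmax": der.qymax,
    }
    for k, (sig, tr) in enumerate(zip(raw.steps, der.steps), start=1):
        out[f"F0p_Lss{k}"] = sig.f0p
        out[f"Ftp_Lss{k}"] = sig.ftp
        out[f"Fmp_Lss{k}"] = sig.fmp
        out[f"Fvp_Lss{k}"] = tr.fvp
        out[f"QYp_Lss{k}"] = tr.qyp
        out[f"NPQ_Lss{k}"] = tr.npq
        out[f"qN_Lss{k}"] = tr.qn
        out[f"qP_Lss{k}"] = tr.qp
        out[f"Fq_Lss{k}"] = tr.fqp
    return out


def assemble_trait_table(records: Iterable[dict]) -> pd.DataFrame:
    """Build the long-format trait table feeding statistics and classification.

    Parameters
    ----------
    records
        Iterable of per-plant-day dicts with keys ``plant_id``, ``genotype``,
        ``treatment``, ``das`` and ``traits`` (a mapping trait name -> value,
        names from :data:`TRAIT_VOCABULARY`).

    Returns
    -------
    DataFrame with columns ``plant_id, genotype, treatment, das, trait,
    value`` — one row per (plant, day, trait).

    Raises
    ------
    ValueError
        On a duplicate (plant, das, trait) combination or a trait name
        outside the vocabulary.
    """
    vocab = set(TRAIT_VOCABULARY)
    rows = []
    for rec in records:
        for name, value in rec["traits"].items():
            if name not in vocab:
                raise ValueError(f"unknown trait name {name!r}")
            rows.append(
                (
                    rec["plant_id"],
                    rec["genotype"],
                    rec["treatment"],
                    int(rec["das"]),
                    name,
                    float(value),
                )
            )
    table = pd.DataFrame(
        rows, columns=["plant_id", "genotype", "treatment", "das", "trait", "value"]
    )
    if len(table):
        dup = table.duplicated(subset=["plant_id", "das", "trait"])
        if dup.any():
            first = table.loc[dup.idxmax()]
            raise ValueError(
                "duplicate trait record for "
                f"({first.plant_id}, das={first.das}, {first.trait})"
            )
    return table


def raw_to_frame(records: Sequence[tuple[str, int, RawFluorescence]]) -> pd.DataFrame:
    """Serialise raw signals to the flat CSV schema.

    Columns: ``plant_id, das, f0, fm, f0p_lss{1..6}, ftp_lss{1..6},
    fmp_lss{1..6}``.
    """
    rows = []
    for plant_id, das, raw in records:
        row: dict[str, object] = {"plant_id": plant_id, "das": int(das), "f0": raw.f0, "fm": raw.fm}
        for k, s in enumerate(raw.steps, start=1):
            row[f"f0p_lss{k}"] = s.f0p
            row[f"ftp_lss{k}"] = s.ftp
            row[f"fmp_lss{k}"] = s.fmp
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_raw(frame: pd.DataFrame) -> list[tuple[str, int, RawFluorescence]]:
    """Inverse of :func:`raw_to_frame`."""
    n_steps = sum(c.startswith("f0p_lss") for c in frame.columns)
    out = []
    for _, row in frame.iterrows():
        steps = tuple(
            LightStepSignal(
                float(row[f"f0p_lss{k}"]), float(row[f"ftp_lss{k}"]), float(row[f"fmp_lss{k}"])
            )
            for k in range(1, n_steps + 1)
        )
        out.append(
            (str(row["plant_id"]), int(row["das"]), RawFluorescence(float(row["f0"]), float(row["fm"]), steps))
        )
    return out
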