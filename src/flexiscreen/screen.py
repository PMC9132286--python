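"""Mutant triage: ΔΔG selection and the two-stage ΔRMSF screen.

Stage 0 consumes a Rosetta-style design table: at each position the design
with the best (most negative) ΔΔG is kept, and only if ΔΔG < 0 REU.
Stage 1 compares mutant against wild-type flexibility at high temperature:
mutants whose region-mean RMSF dropped by strictly more than 10 % (ΔRMSF
< −10.0 %) advance. Stage 2 repeats the comparison at the enzyme's optimum
temperature with a sign threshold (ΔRMSF < 0).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import RmsfProfile
from .io import DesignRecord
from .regions import FlexibleRegion

__all__ = [
    "MutantCall",
    "DeltaRmsfResult",
    "select_designs",
    "region_delta_rmsf",
    "replicate_delta_rmsf",
    "screen_stage",
]

#: Stage-1 pass rule: region-mean RMSF strictly more than 10 % below wild type.
HIGH_TEMP_DELTA_RMSF_THRESHOLD = -10.0
#: Stage-2 pass rule: any flexibility reduction at the optimum temperature.
OPTIMUM_TEMP_DELTA_RMSF_THRESHOLD = 0.0

_LABEL_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class MutantCall:
    """One selected point mutation, labelled native aa + position + designed aa (e.g. N88Q)."""

    label: str
    region_id: int
    ddG: float

    def __post_init__(self):
        if _LABEL_RE.match(self.label) is None:
            raise ValueError(f"label {self.label!r} is not of the form N88Q")
        if not self.ddG < 0:
            raise ValueError(f"{self.label}: selected mutants require ΔΔG < 0 REU")

    @property
    def native_aa(self) -> str:
        return _LABEL_RE.match(self.label).group(1)

    @property
    def residue_number(self) -> int:
        return int(_LABEL_RE.match(self.label).group(2))

    @property
    def designed_aa(self) -> str:
        return _LABEL_RE.match(self.label).group(3)


@dataclass(frozen=True)
class DeltaRmsfResult:
    """Replicate-averaged regional ΔRMSF (%) for one mutant at one temperature."""

    mutant_label: str
    temperature_label: str
    mean_delta_rmsf: float
    sem_delta_rmsf: float
    threshold: float
    region_id: int = 0

    @property
    def passes(self) -> bool:
        return self.mean_delta_rmsf < self.threshold


def select_designs(records: Sequence[DesignRecord]) -> list[MutantCall]:
    """Best-ΔΔG-per-position selection under the ΔΔG < 0 REU rule.

    Positions whose design is absent or identical to the native residue are
    skipped; at most one call per position survives (minimum ΔΔG, ties to
    the alphabetically first designed residue). Conflicting duplicate rows
    are an error.
    """
    seen: dict[tuple[int, str], float] = {}
    by_position: dict[int, list[DesignRecord]] = {}
    for rec in records:
        if rec.designed_aa is None or rec.ddG is None or rec.designed_aa == rec.native_aa:
            continue
        key = (rec.residue_number, rec.designed_aa)
        if key in seen and seen[key] != rec.ddG:
            raise ValueError(f"conflicting ΔΔG values for {rec.native_aa}"
                             f"{rec.residue_number}{rec.designed_aa}")
        seen[key] = rec.ddG
        by_position.setdefault(rec.residue_number, []).append(rec)
    calls = []
    for pos in sorted(by_position):
        best = min(by_position[pos], key=lambda r: (r.ddG, r.designed_aa))
        if best.ddG < 0:
            calls.append(MutantCall(f"{best.native_aa}{pos}{best.designed_aa}",
                                    best.region_id, best.ddG))
    return calls


def region_delta_rmsf(mutant_profile: RmsfProfile, wildtype_profile: RmsfProfile,
                      region: FlexibleRegion) -> float:
    """Percent change of region-mean RMSF, mutant relative to wild type.

    ``100 × (mean_mut − mean_wt) / mean_wt`` over the region's residues.
    """
    wt = wildtype_profile.region_mean(region.start_residue, region.end_residue)
    mut = mutant_profile.region_mean(region.start_residue, region.end_residue)
    if wt == 0:
        raise ZeroDivisionError("wild-type region-mean RMSF is zero: ΔRMSF undefined")
    return 100.0 * (mut - wt) / wt


def replicate_delta_rmsf(mutant_profiles: Sequence[RmsfProfile],
                         wildtype_profiles: Sequence[RmsfProfile],
                         region: FlexibleRegion,
                         mutant_label: str = "",
                         temperature_label: str = "",
                         threshold: float = HIGH_TEMP_DELTA_RMSF_THRESHOLD
                         ) -> DeltaRmsfResult:
    """Mean ± SEM of ΔRMSF over replicate pairings.

    Equal replicate counts pair index-wise (replicate i vs replicate i);
    unequal counts fall back to all pairs. SEM is the sample standard
    deviation of the pair values over √n (0 for a single pair).
    """
    if not mutant_profiles or not wildtype_profiles:
        raise ValueError("need at least one replicate on each side")
    if len(mutant_profiles) == len(wildtype_profiles):
        pairs = list(zip(mutant_profiles, wildtype_profiles))
    else:
        pairs = [(m, w) for m in mutant_profiles for w in wildtype_profiles]
    values = np.array([region_delta_rmsf(m, w, region) for m, w in pairs])
    sem = float(np.std(values, ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return DeltaRmsfResult(mutant_label, temperature_label,
                           float(np.mean(values)), sem, threshold, region.region_id)


def screen_stage(results: Sequence[DeltaRmsfResult], threshold: float) -> list[str]:
    """Labels of mutants whose mean ΔRMSF is strictly below the threshold, order preserved.

    All results must carry the same temperature label (one stage at a time).
    """
    temperatures = {r.temperature_label for r in results}
    if len(temperatures) > 1:
        raise ValueError(f"mixed temperature labels in one stage: {sorted(temperatures)}")
    return [r.mutant_label for r in results if r.mean_delta_rmsf < threshold]
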