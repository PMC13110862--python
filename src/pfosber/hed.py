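"""Human-equivalent doses, reference exposures and bioactivity exposure ratios.

The chain from an in vitro benchmark concentration to a human-relevant daily
intake is linear:

    HED (ng/kg bw/day) = BMC (nM) × MW/1000 (→ ng/ml) × dose_factor

where ``dose_factor`` (ng/kg bw/day per ng/ml of ovarian interstitial fluid)
is the reciprocal of the PBTK dose→concentration factor, calibrated against
the published anchor pair (181 ng/ml ↔ 172 ng/kg bw/day, i.e. ≈ 0.9503).

Reference exposures come from two populations: women undergoing ART, whose
follicular-fluid PFOS levels are measured directly, and occupationally
exposed women, whose follicular-fluid levels are predicted from serum via
the blood-to-follicular-fluid transfer efficiency (C_ff = C_serum × BFTE,
BFTE = 0.75).  The bioactivity exposure ratio is

    BER = HED_bioactive / HED_reference

with BER < 1 meaning real-world exposure reaches bioactive levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from pfosber.bmc import summarize_bmcs
from pfosber.units import MW_PFOS_ACID, nM_to_ng_per_ml

#: ng/kg bw/day per ng/ml ovarian interstitial fluid; anchor-calibrated
#: (reciprocal of 181/172) — the mechanistic pbtk route reproduces it after
#: calibrate_to_anchor
DEFAULT_DOSE_FACTOR = 172.0 / 181.0

BFTE_DEFAULT = 0.75


@dataclass(frozen=True)
class ReferenceExposure:
    """Population reference exposure on concentration and HED scales."""

    population: str  # "ART" or "occupational"
    conc_min: float  # ng/ml follicular fluid
    conc_median: float
    conc_max: float
    hed_min: float  # ng/kg bw/day
    hed_median: float
    hed_max: float
    bfte: Optional[float] = None  # set when built from serum
    serum: Optional[tuple] = None  # (min, median, max) ng/ml

    def __post_init__(self):
        if not self.conc_min <= self.conc_median <= self.conc_max:
            raise ValueError("reference concentrations must be ordered min <= median <= max")
        if not self.hed_min <= self.hed_median <= self.hed_max:
            raise ValueError("reference HEDs must be ordered min <= median <= max")


@dataclass
class BERRecord:
    endpoint_id: str
    hed_bioactive: float
    reference_id: str
    ber_at_median_ref: float
    ber_interval: tuple  # (at max reference, at min reference)
    below_one_median: bool  # BER at the median reference < 1
    below_one_interval: bool  # whole interval below 1 (even at the min reference)


def bmc_to_hed(bmc_nM: float, mw: float = MW_PFOS_ACID,
               dose_factor: float = DEFAULT_DOSE_FACTOR) -> float:
    """Daily oral intake producing a BMC-equivalent ovarian interstitial level."""
    if dose_factor <= 0:
        raise ValueError("dose_factor must be positive")
    return nM_to_ng_per_ml(bmc_nM, mw) * dose_factor


def hed_to_bmc(hed: float, mw: float = MW_PFOS_ACID,
               dose_factor: float = DEFAULT_DOSE_FACTOR) -> float:
    """Exact inverse of :func:`bmc_to_hed` (ng/kg bw/day → nM)."""
    return hed / dose_factor * 1000.0 / mw


def reference_from_serum(serum_values: Sequence[float], bfte: float = BFTE_DEFAULT,
                         dose_factor: float = DEFAULT_DOSE_FACTOR,
                         population: str = "occupational") -> ReferenceExposure:
    """Build a reference exposure from (min, median, max) serum levels.

    Follicular-fluid concentrations are ``serum × BFTE``; HEDs follow by
    reverse dosimetry (``conc × dose_factor``).
    """
    if not 0.0 < bfte <= 1.0:
        raise ValueError("bfte must be in (0, 1]")
    s = sorted(float(v) for v in serum_values)
    if len(s) != 3 or s[0] < 0:
        raise ValueError("serum_values must be three non-negative numbers")
    conc = [v * bfte for v in s]
    hed = [c * dose_factor for c in conc]
    return ReferenceExposure(population, *conc, *hed, bfte=bfte, serum=tuple(s))


def reference_from_heds(hed_values: Sequence[float],
                        dose_factor: float = DEFAULT_DOSE_FACTOR,
                        population: str = "ART") -> ReferenceExposure:
    """Build a reference directly from (min, median, max) HEDs (ART style)."""
    h = sorted(float(v) for v in hed_values)
    conc = [v / dose_factor for v in h]
    return ReferenceExposure(population, *conc, *h)


def ber(hed_bioactive: float, hed_reference: float) -> float:
    """Bioactivity exposure ratio (full precision; round for reporting)."""
    if hed_reference <= 0:
        raise ValueError("reference HED must be positive")
    return hed_bioactive / hed_reference


def ber_interval(endpoint_id: str, hed_bioactive: float,
                 reference: ReferenceExposure) -> BERRecord:
    """BER at the median reference plus the (max-ref, min-ref) interval."""
    if min(reference.hed_min, reference.hed_median, reference.hed_max) <= 0:
        raise ValueError("all reference HEDs must be positive")
    b_med = hed_bioactive / reference.hed_median
    lo = hed_bioactive / reference.hed_max
    hi = hed_bioactive / reference.hed_min
    return BERRecord(
        endpoint_id=endpoint_id,
        hed_bioactive=hed_bioactive,
        reference_id=reference.population,
        ber_at_median_ref=b_med,
        ber_interval=(lo, hi),
        below_one_median=b_med < 1.0,
        below_one_interval=hi < 1.0,
    )


def flag_low_ber_genes(gene_heds: dict, reference_hed: float,
                       threshold: float = 1.0) -> list[str]:
    """Genes whose HED falls below ``threshold × reference``, most sensitive first."""
    if reference_hed <= 0:
        raise ValueError("reference HED must be positive")
    flagged = [(g, h / reference_hed) for g, h in gene_heds.items()
               if h / reference_hed < threshold]
    flagged.sort(key=lambda t: (t[1], t[0]))
    return [g for g, _ in flagged]


def aggregate_pathway_hed(gene_heds: dict, gene_set: Sequence[str]) -> Optional[float]:
    """Pathway-level HED = median HED over member genes with an estimate.

    Returns ``None`` when the set shares no gene with the map.  The median of
    two values is their mean (numpy convention).
    """
    vals = [gene_heds[g] for g in set(gene_set) if g in gene_heds]
    if not vals:
        return None
    return float(np.median(vals))


def summarize_heds(heds: Sequence[float], stat: str = "median",
                   bootstrap_B: int = 1000, seed=0):
    """Median or 5th-percentile HED with a seeded percentile-bootstrap 95% CI."""
    return summarize_bmcs(list(heds), stat=stat, bootstrap_B=bootstrap_B, seed=seed)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes…"""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def ber_report(records: Sequence[BERRecord]) -> pd.DataFrame:
    """Tabular BER report; ratios rounded to one decimal for reporting."""
    return pd.DataFrame(
        {
            "endpoint": [r.endpoint_id for r in records],
            "hed": [r.hed_bioactive for r in records],
            "reference": [r.reference_id for r in records],
            "ber_median": [round(r.ber_at_median_ref, 1) for r in records],
            "ber_min": [round(r.ber_interval[0], 1) for r in records],
            "ber_max": [round(r.ber_interval[1], 1) for r in records],
            "below_one": [r.below_one_median for r in records],
        }
    )
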