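"""Unit conversions bridging molar in vitro concentrations and mass-based PBTK output.

BMCs are estimated in nM (the in vitro exposure scale); the toxicokinetic model
and all human exposure references work in ng/ml.  The bridge is the molecular
weight: ng/ml = nM × MW / 1000.
"""

from __future__ import annotations

from dataclasses import dataclass

#: PFOS free acid, g/mol.  The default: only the acid MW makes the published
#: nM ↔ ng/kg bw/day chain internally consistent.
MW_PFOS_ACID = 500.13

#: PFOS potassium salt, g/mol (the form usually dosed in vitro); selectable.
MW_PFOS_K_SALT = 538.22


@dataclass(frozen=True)
class UnitConversion:
    """Molar↔mass conversion settings for a single compound."""

    molecular_weight: float = MW_PFOS_ACID

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")

    def to_ng_per_ml(self, conc_nM: float) -> float:
        return nM_to_ng_per_ml(conc_nM, self.molecular_weight)

    def to_nM(self, conc_ng_ml: float) -> float:
        return ng_per_ml_to_nM(conc_ng_ml, self.molecular_weight)


def nM_to_ng_per_ml(conc_nM, mw: float = MW_PFOS_ACID):
    """Convert a concentration in nmol/l to ng/ml.

    Accepts scalars or numpy arrays; negative concentrations are rejected.
    """
    import numpy as np

    c = np.asarray(conc_nM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    out = c * mw / 1000.0
    return float(out) if out.ndim == 0 else out


def ng_per_ml_to_nM(conc_ng_ml, mw: float = MW_PFOS_ACID):
    """Exact inverse of :func:`nM_to_ng_per_ml`."""
    import numpy as np

    c = np.asarray(conc_ng_ml, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    out = c * 1000.0 / mw
    return float(out) if out.ndim == 0 else out
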