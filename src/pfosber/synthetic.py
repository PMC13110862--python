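"""Synthetic concentration-response data with known ground truth.

Emulates the structure of the study system this package is built around:
human granulosa cells exposed for weeks to PFOS at 0, 0.01, 0.1 and 1 µM
(stored internally as 0/10/100/1000 nM), four biological replicates per
concentration, expression on the log2 scale.  A minority of "responder" genes
follow a planted monotone dose-response curve (Hill, Exp5 or Linear); all
other genes are flat.  Noise is additive Gaussian on the log2 scale.

Each responder carries a :class:`TruthRecord` whose ``true_bmc`` is the
analytic benchmark concentration of the planted curve at a benchmark response
of 1 noise SD — the oracle every downstream estimate is judged against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from pfosber.matrix import ExpressionMatrix
from pfosber.models import evaluate_model


@dataclass(frozen=True)
class SyntheticDesign:
    """Experimental design of a simulated concentration-response study.

    ``concentrations`` are in nM unless ``concentration_unit="uM"`` is given,
    in which case they are converted at construction; internally everything
    is nM.
    """

    concentrations: tuple = (0.0, 10.0, 100.0, 1000.0)
    n_replicates: int = 4
    n_genes: int = 500
    responder_fraction: float = 0.1
    noise_sd: float = 0.25
    seed: int = 0
    concentration_unit: str = "nM"

    def __post_init__(self):
        if self.concentration_unit not in ("nM", "uM"):
            raise ValueError("concentration_unit must be 'nM' or 'uM'")
        conc = tuple(float(c) for c in self.concentrations)
        if self.concentration_unit == "uM":
            conc = tuple(c * 1000.0 for c in conc)
            object.__setattr__(self, "concentration_unit", "nM")
        object.__setattr__(self, "concentrations", conc)
        if len(conc) < 2 or any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly increasing")
        if conc[0] != 0.0:
            raise ValueError("concentration grid must include 0 (control)")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per concentration")
        if self.n_genes < 1:
            raise ValueError("need >= 1 gene")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_responders(self) -> int:
        return int(round(self.responder_fraction * self.n_genes))

    @property
    def max_dose(self) -> float:
        return self.concentrations[-1]


@dataclass
class TruthRecord:
    """Ground truth for one simulated gene."""

    gene_id: str
    is_responder: bool
    model_id: Optional[str] = None  # Hill | Exp5 | Linear
    params: dict = field(default_factory=dict)  # includes "sigma" = planted noise SD
    direction: int = 0  # +1 up, -1 down, 0 non-responder
    true_bmc: Optional[float] = None

    def mean_at(self, dose) -> np.ndarray:
        if not self.is_responder:
            return np.full_like(np.asarray(dose, dtype=float), self.params["baseline"])
        p = {k: v for k, v in self.params.items() if k not in ("sigma", "baseline")}
        return evaluate_model(self.model_id, p, dose)


def true_bmc(truth: TruthRecord, bmr_sd: float = 1.0) -> Optional[float]:
    """Analytic BMC of a planted curve: smallest d>0 with |f(d) − f(0)| = bmr_sd·σ.

    Returns ``None`` when the planted amplitude never reaches the benchmark
    response.  Closed forms per model:

    * Linear: ``B/|β1|``
    * Hill:   ``k·(x/(1−x))^(1/n)`` with ``x = B/|v|``
    * Exp5:   ``(−ln(1−x))^(1/g) / b`` with ``x = B/|a(c−1)|``
    """
    if not truth.is_responder:
        raise ValueError("true_bmc is defined only for responders")
    if bmr_sd <= 0:
        raise ValueError("bmr_sd must be positive")
    B = bmr_sd * truth.params["sigma"]
    p = truth.params
    if truth.model_id == "Linear":
        if p["beta1"] == 0:
            return None
        return B / abs(p["beta1"])
    if truth.model_id == "Hill":
        x = B / abs(p["v"])
        if x >= 1.0:
            return None
        return p["k"] * (x / (1.0 - x)) ** (1.0 / p["n"])
    if truth.model_id == "Exp5":
        amp = abs(p["a"] * (p["c"] - 1.0))
        if amp == 0:
            return None
        x = B / amp
        if x >= 1.0:
            return None
        return (-np.log(1.0 - x)) ** (1.0 / p["g"]) / p["b"]
    raise ValueError(f"no analytic BMC for model {truth.model_id!r}")


def _draw_responder(rng: np.random.Generator, gene_id: str, design: SyntheticDesign,
                    models: Sequence[str], amplitude_range, ec50_range,
                    hill_n_range, exp_g_range) -> TruthRecord:
    model_id = models[rng.integers(len(models))] if len(models) > 1 else models[0]
    direction = int(rng.choice([-1, 1]))
    baseline = float(rng.uniform(6.0, 10.0))
    amp = float(rng.uniform(*amplitude_range))
    ec50 = float(np.exp(rng.uniform(np.log(ec50_range[0]), np.log(ec50_range[1]))))
    params: dict = {"sigma": design.noise_sd}
    if model_id == "Hill":
        params.update(gamma=baseline, v=direction * amp,
                      k=ec50, n=float(rng.uniform(*hill_n_range)))
    elif model_id == "Exp5":
        # asymptotic shift a·(c−1) equals ±amp exactly
        c = 1.0 + direction * amp / baseline
        if c <= 0:
            c = 0.05
        params.update(a=baseline, b=1.0 / ec50, c=c, g=float(rng.uniform(*exp_g_range)))
    elif model_id == "Linear":
        params.update(beta0=baseline, beta1=direction * amp / design.max_dose)
    else:
        raise ValueError(model_id)
    rec = TruthRecord(gene_id, True, model_id, params, direction)
    rec.true_bmc = true_bmc(rec, 1.0)
    return rec


def generate_expression_matrix(
    design: SyntheticDesign,
    models: Sequence[str] = ("Hill", "Exp5", "Linear"),
    amplitude_range=(1.5, 2.5),
    ec50_range=(30.0, 1000.0),
    hill_n_range=(1.0, 3.0),
    exp_g_range=(1.0, 2.0),
):
    """Simulate a gene × sample log2 matrix plus its ground-truth records.

    Responders (the first ``design.n_responders`` genes after a seeded
    shuffle) follow their planted curve; all genes get i.i.d. N(0, noise_sd²)
    log2 noise.  Bit-identical under a fixed seed.
    """
    rng = np.random.default_rng(design.seed)
    conc = np.repeat(design.concentrations, design.n_replicates)
    gene_ids = [f"G{i:05d}" for i in range(design.n_genes)]
    responder_idx = set(rng.choice(design.n_genes, size=design.n_responders, replace=False).tolist())

    truths: list[TruthRecord] = []
    means = np.empty((design.n_genes, conc.size))
    for i, gid in enumerate(gene_ids):
        if i in responder_idx:
            rec = _draw_responder(rng, gid, design, models, amplitude_range,
                                  ec50_range, hill_n_range, exp_g_range)
        else:
            rec = TruthRecord(gid, False, None,
                              {"baseline": float(rng.uniform(6.0, 10.0)),
                               "sigma": design.noise_sd}, 0, None)
        truths.append(rec)
        means[i] = rec.mean_at(conc)

    values = means + rng.normal(0.0, design.noise_sd, size=means.shape)
    mat = ExpressionMatrix(gene_ids=gene_ids, values=values, concentrations=conc)
    return mat, truths


def generate_apical_table(design: SyntheticDesign, endpoint_specs: dict) -> pd.DataFrame:
    """Simulate apical endpoint summaries (endpoint × concentration × replicate).

    ``endpoint_specs`` maps endpoint name → dict with keys ``model_id``
    (Hill/Exp5/Linear or ``"flat"``), ``params`` (curve parameters; ``baseline``
    for flat) and ``noise_sd``.  Long-format output with columns
    endpoint, concentration_nM, replicate, value.
    """
    if not endpoint_specs:
        raise ValueError("endpoint_specs must not be empty")
    rng = np.random.default_rng(design.seed)
    rows = []
    for name, spec in endpoint_specs.items():
        noise = float(spec.get("noise_sd", design.noise_sd))
        model_id = spec["model_id"]
        for c in design.concentrations:
            if model_id == "flat":
                mu = float(spec["params"]["baseline"])
            else:
                p = {k: v for k, v in spec["params"].items() if k != "sigma"}
                mu = float(evaluate_model(model_id, p, c))
            for j in range(design.n_replicates):
                rows.append((name, c, j + 1, mu + rng.normal(0.0, noise)))
    return pd.DataFrame(rows, columns=["endpoint", "concentration_nM", "replicate", "value"])


def apical_table_to_matrix(table: pd.DataFrame) -> ExpressionMatrix:
    """Reshape a long apical table into the endpoint × sample container so the
    trend screen and BMC fitter can run on it unchanged."""
    wide = table.pivot_table(index="endpoint", columns=["concentration_nM", "replicate"],
                             values="value", sort=True)
    conc = np.array([c for c, _ in wide.columns])
    reps = [str(r) for _, r in wide.columns]
    return ExpressionMatrix(gene_ids=[str(e) for e in wide.index],
                            values=wide.to_numpy(), concentrations=conc, replicates=reps)


def truth_table(truths: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in truths],
            "is_responder": [t.is_responder for t in truths],
            "model_id": [t.model_id for t in truths],
            "direction": [t.direction for t in truths],
            "true_bmc": [t.true_bmc for t in truths],
            "params": [json.dumps(t.params) for t in truths],
        }
    )


def printed_values_fixture() -> dict:
    """Published summary constants of the PFOS granulosa-cell study.

    These are the externally reported quantities the package's acceptance
    checks reproduce through the computation chain (units as published:
    BMCs nM; HEDs ng/kg bw/day; concentrations ng/ml).
    """
    return {
        # median BMCs: 6/12-week transcriptomic and 12-week apical lie in
        # [36.5, 38.1] nM; the 6-week apical median is 214 nM
        "median_bmc_transcriptomic_6wk_nM": 38.1,
        "median_bmc_low_nM": 36.5,
        "median_bmc_apical_6wk_nM": 214.0,
        # median HEDs (uncorrected)
        "median_hed_transcriptomic_6wk": 18.1,
        "median_hed_transcriptomic_12wk": 17.5,
        "median_hed_apical_12wk": 17.3,
        "median_hed_apical_6wk": 101.7,
        "p5_hed_transcriptomic_6wk": 3.7,
        "p5_hed_transcriptomic_12wk": 1.4,
        "pathway_hed_min": 2.8,
        "pathway_hed_max": 24.1,
        "apical_hed_subg1": 0.4,
        "apical_hed_estradiol": 203.0,
        # albumin-corrected medians
        "corrected_hed_transcriptomic_6wk": 302.0,
        "corrected_hed_transcriptomic_12wk": 291.8,
        "corrected_p5_hed_6wk": 61.7,
        "corrected_p5_hed_12wk": 22.6,
        "corrected_pathway_hed_min": 45.8,
        "corrected_pathway_hed_max": 401.6,
        "corrected_hed_apical_6wk": 1694.7,
        "corrected_hed_apical_12wk": 289.0,
        # reference exposures (HED scale, ng/kg bw/day)
        "ART_ref_min": 0.1,
        "ART_ref_median": 3.5,
        "ART_ref_max": 172.0,
        "occupational_ref": (303.6, 877.3, 13942.7),
        # raw exposure concentrations
        "occupational_serum_ng_ml": (426.0, 1231.0, 19564.0),
        "follicular_fluid_range_ng_ml": (0.1, 181.0),
        # physiological constants
        "fu_plasma": 0.0033,
        "bfte": 0.75,
    }


def write_fixture_json(path) -> None:
    with open(path, "w") as fh:
        json.dump(printed_values_fixture(), fh, indent=2)
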