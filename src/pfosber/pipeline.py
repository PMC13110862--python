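"""End-to-end orchestration: screen → fit → filter → correct → HED → BER.

A single YAML config drives every stage; all randomness is seeded from one
``seed`` key so a re-run with the same config is bit-identical.  Each stage
writes plain TSV/JSON so it can be re-run independently, and a manifest
records parameters, seeds and per-stage record counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pfosber import bmc as bmcmod
from pfosber import binding, hed, pbtk, synthetic, trend
from pfosber.matrix import ExpressionMatrix
from pfosber.units import MW_PFOS_ACID

log = logging.getLogger("pfosber")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "pfosber_out",
    "inputs": {"expression_tsv": None, "gene_sets_gmt": None},
    "synthetic": {
        "concentrations": [0.0, 10.0, 100.0, 1000.0],
        "n_replicates": 4,
        "n_genes": 300,
        "responder_fraction": 0.1,
        "noise_sd": 0.25,
    },
    "screen": {"alpha": 0.05, "fc_threshold": 1.5, "B": 500},
    "fit": {"bmr_sd": 1.0, "p_nested": 0.05, "restricted": True,
            "ratio_max": 40.0, "bootstrap_B": 1000},
    "correction": {"enabled": True, "fu_plasma": binding.FU_PLASMA_DEFAULT,
                   "fu_invitro": binding.FU_INVITRO_DEFAULT,
                   "albumin_plasma": None, "albumin_invitro": None},
    "pbtk": {"calibrate": True, "anchor_conc": pbtk.ANCHOR_CONC_NG_ML,
             "anchor_dose": pbtk.ANCHOR_DOSE_NG_KG_DAY, "time_step": 0.05,
             "params": {}, "regimen": {}},
    "units": {"molecular_weight": MW_PFOS_ACID},
    "references": {
        "ART": {"heds": [0.1, 3.5, 172.0]},
        "occupational": {"serum": [426.0, 1231.0, 19564.0], "bfte": hed.BFTE_DEFAULT},
    },
}


def load_config(path=None) -> dict:
    """Merge a YAML config file over the defaults (shallow, per section)."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def build_dose_factor(cfg: dict) -> float:
    """ng/kg bw/day per ng/ml from the (optionally anchor-calibrated) PBTK model."""
    pc = cfg["pbtk"]
    params = pbtk.PBTKParameters(**pc.get("params", {}))
    regimen = pbtk.DosingRegimen(**pc.get("regimen", {}))
    if pc.get("calibrate", True):
        params = pbtk.calibrate_to_anchor(params, pc["anchor_conc"], pc["anchor_dose"],
                                          regimen, pc["time_step"])
    conc_per_dose = pbtk.dose_to_conc_factor(params, regimen, pc["time_step"])
    return 1.0 / conc_per_dose


def run_pipeline(cfg: dict, output_dir=None) -> dict:
    """Execute the full chain and return the run manifest (also written to disk)."""
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"seed": seed, "config": cfg, "stages": {}, "outputs": []}

    def save(df: pd.DataFrame, name: str, index=False):
        p = out / name
        df.to_csv(p, sep="\t", index=index)
        manifest["outputs"].append(str(p))
        return p

    # --- data -------------------------------------------------------------
    if cfg["inputs"].get("expression_tsv"):
        matrix = ExpressionMatrix.from_tsv(cfg["inputs"]["expression_tsv"])
        truths = None
        log.info("loaded expression matrix: %d genes, %d samples", matrix.n_genes, matrix.n_samples)
    else:
        design = synthetic.SyntheticDesign(seed=seed, **{
            k: tuple(v) if k == "concentrations" else v for k, v in cfg["synthetic"].items()
        })
        matrix, truths = synthetic.generate_expression_matrix(design)
        matrix.to_tsv(out / "expression_matrix.tsv")
        save(synthetic.truth_table(truths), "truth.tsv")
        log.info("simulated %d genes (%d responders)", design.n_genes, design.n_responders)
    manifest["stages"]["data"] = {"n_genes": matrix.n_genes, "n_samples": matrix.n_samples}

    # --- screen -----------------------------------------------------------
    sc = cfg["screen"]
    screen = trend.screen_probes(matrix, alpha=sc["alpha"], fc_threshold=sc["fc_threshold"],
                                 B=sc["B"], seed=seed)
    save(screen, "screen_results.tsv")
    n_pass = int(screen["passes"].sum())
    manifest["stages"]["screen"] = {"n_pass": n_pass, **sc}
    log.info("screen: %d/%d genes pass", n_pass, matrix.n_genes)

    # --- BMC fitting ------------------------------------------------------
    fc = cfg["fit"]
    max_dose = float(matrix.dose_levels[-1])
    records = []
    passing = screen.loc[screen["passes"], "gene_id"]
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    for gid in passing:
        rec = bmcmod.fit_endpoint(gid, matrix.concentrations, matrix.values[gene_index[gid]],
                                  bmr_sd=fc["bmr_sd"], p_nested=fc["p_nested"],
                                  restricted=fc["restricted"])
        if rec is not None:
            records.append(rec)
    retained = bmcmod.filter_bmc_records(records, max_dose, fc["ratio_max"])
    save(bmcmod.records_to_frame(records), "bmc_records.tsv")
    manifest["stages"]["fit"] = {"n_fit": len(records), "n_retained": len(retained)}
    log.info("fit: %d endpoints modelled, %d retained after filters", len(records), len(retained))

    # --- binding correction -----------------------------------------------
    cc = cfg["correction"]
    factor = None
    corrected = []
    if cc.get("enabled", True):
        cp = binding.CorrectionParams(fu_plasma=cc["fu_plasma"], fu_invitro=cc["fu_invitro"],
                                      albumin_plasma=cc.get("albumin_plasma"),
                                      albumin_invitro=cc.get("albumin_invitro"))
        factor = binding.correction_factor(cp)
        corrected = [binding.apply_correction(r, factor) for r in retained]
        save(bmcmod.records_to_frame(corrected), "bmc_records_corrected.tsv")
    manifest["stages"]["correction"] = {"enabled": bool(cc.get("enabled", True)), "factor": factor}

    # --- reverse dosimetry + HED -------------------------------------------
    dose_factor = build_dose_factor(cfg)
    mw = cfg["units"]["molecular_weight"]
    gene_heds = {r.endpoint_id: hed.bmc_to_hed(r.bmc, mw, dose_factor) for r in retained}
    hed_df = pd.DataFrame({"gene_id": list(gene_heds), "hed": list(gene_heds.values())})
    save(hed_df, "gene_heds.tsv")
    manifest["stages"]["hed"] = {"dose_factor": dose_factor, "molecular_weight": mw,
                                 "n_heds": len(gene_heds)}
    log.info("hed: dose factor %.5f ng/kg bw/day per ng/ml, %d endpoint HEDs",
             dose_factor, len(gene_heds))

    # --- references + BER ---------------------------------------------------
    refs = {}
    rc = cfg["references"]
    if "ART" in rc:
        refs["ART"] = hed.reference_from_heds(rc["ART"]["heds"], dose_factor, "ART")
    if "occupational" in rc:
        refs["occupational"] = hed.reference_from_serum(rc["occupational"]["serum"],
                                                        rc["occupational"]["bfte"], dose_factor)
    summary: dict = {"dose_factor": dose_factor, "correction_factor": factor}
    ber_records = []
    if gene_heds:
        med, lo95, hi95 = hed.summarize_heds(list(gene_heds.values()), "median",
                                             cfg["fit"]["bootstrap_B"], seed)
        p5, p5lo, p5hi = hed.summarize_heds(list(gene_heds.values()), "p5",
                                            cfg["fit"]["bootstrap_B"], seed)
        summary["median_hed"] = {"estimate": med, "ci": [lo95, hi95]}
        summary["p5_hed"] = {"estimate": p5, "ci": [p5lo, p5hi]}
        for name, ref in refs.items():
            ber_records.append(hed.ber_interval("median_hed", med, ref))
            ber_records.append(hed.ber_interval("p5_hed", p5, ref))
        if "ART" in refs:
            summary["low_ber_genes"] = hed.flag_low_ber_genes(gene_heds, refs["ART"].hed_median)

    # pathway aggregation when gene sets are supplied
    gmt_path = cfg["inputs"].get("gene_sets_gmt")
    if gmt_path and gene_heds:
        pathway_heds = {}
        for name, members in hed.read_gmt(gmt_path).items():
            ph = hed.aggregate_pathway_hed(gene_heds, members)
            if ph is not None:
                pathway_heds[name] = ph
                for rname, ref in refs.items():
                    ber_records.append(hed.ber_interval(f"pathway:{name}", ph, ref))
        summary["pathway_heds"] = pathway_heds

    if ber_records:
        save(hed.ber_report(ber_records), "ber_report.tsv")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    manifest["outputs"].append(str(out / "summary.json"))
    manifest["stages"]["ber"] = {"n_records": len(ber_records)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# printed-chain acceptance report
# ---------------------------------------------------------------------------

def acceptance_report(fixture: dict | None = None, dose_factor: float | None = None,
                      rel_tol: float = 0.02) -> pd.DataFrame:
    """Recompute the published summary chain and compare with printed values.

    Every row computes a quantity through the package (unit conversion,
    anchor-calibrated reverse dosimetry, BFTE scaling, binding correction,
    BER division) and compares it against the corresponding printed constant
    from :func:`pfosber.synthetic.printed_values_fixture`.
    """
    if fixture is None:
        fixture = synthetic.printed_values_fixture()
    if not fixture:
        return pd.DataFrame(columns=["target", "computed", "printed", "rel_error", "passed"])
    if dose_factor is None:
        dose_factor = build_dose_factor(load_config())
    mw = MW_PFOS_ACID
    rows = []

    def add(name, computed, printed, tol=rel_tol, absolute=False):
        err = abs(computed - printed) if absolute else abs(computed - printed) / abs(printed)
        rows.append((name, computed, printed, err, err <= tol))

    # BMC -> HED conversion on the printed 6-week transcriptomic median
    add("median_hed_from_bmc_6wk",
        hed.bmc_to_hed(fixture["median_bmc_transcriptomic_6wk_nM"], mw, dose_factor),
        fixture["median_hed_transcriptomic_6wk"])
    # 6-week apical median BMC recovered from the two printed apical HEDs
    apical_bmcs = [hed.hed_to_bmc(fixture["apical_hed_subg1"], mw, dose_factor),
                   hed.hed_to_bmc(fixture["apical_hed_estradiol"], mw, dose_factor)]
    add("median_apical_bmc_6wk_nM", float(np.median(apical_bmcs)),
        fixture["median_bmc_apical_6wk_nM"])
    # occupational reference HEDs from serum × BFTE × dose factor
    occ = hed.reference_from_serum(fixture["occupational_serum_ng_ml"],
                                   fixture["bfte"], dose_factor)
    add("occupational_ref_hed_median", occ.hed_median, fixture["occupational_ref"][1])
    add("occupational_ref_hed_min", occ.hed_min, fixture["occupational_ref"][0])
    # one-decimal BERs from printed HED/reference pairs
    art_median = fixture["ART_ref_median"]
    add("ber_p5_12wk", round(hed.ber(fixture["p5_hed_transcriptomic_12wk"], art_median), 1),
        0.4, tol=0.05, absolute=True)
    add("ber_pathway_min", round(hed.ber(fixture["pathway_hed_min"], art_median), 1),
        0.8, tol=0.05, absolute=True)
    add("ber_subg1", round(hed.ber(fixture["apical_hed_subg1"], art_median), 1),
        0.1, tol=0.05, absolute=True)
    # all occupational BERs below 1
    endpoint_heds = [fixture[k] for k in (
        "median_hed_transcriptomic_6wk", "median_hed_transcriptomic_12wk",
        "median_hed_apical_12wk", "median_hed_apical_6wk",
        "p5_hed_transcriptomic_6wk", "p5_hed_transcriptomic_12wk",
        "pathway_hed_min", "pathway_hed_max", "apical_hed_subg1", "apical_hed_estradiol")]
    max_occ_ber = max(hed.ber(h, occ.hed_min) for h in endpoint_heds)
    add("max_occupational_ber_below_one", float(max_occ_ber < 1.0), 1.0, tol=0.0, absolute=True)
    # albumin correction factor rounds to the printed ~17-fold
    cf = binding.correction_factor(binding.CorrectionParams(fu_plasma=fixture["fu_plasma"]))
    add("albumin_factor_rounded", float(round(cf)), 17.0, tol=0.0, absolute=True)
    # ART minimum reference HED from the printed follicular-fluid minimum
    add("art_ref_hed_min",
        pbtk.hed_for_target_conc(fixture["follicular_fluid_range_ng_ml"][0], 1.0 / dose_factor),
        fixture["ART_ref_min"], tol=0.05, absolute=True)

    return pd.DataFrame(rows, columns=["target", "computed", "printed", "rel_error", "passed"])
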