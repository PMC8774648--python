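"""End-to-end orchestration of the full binding/structure/function analysis.

Given a config pointing at per-ligand input tables, the pipeline runs, in
order: inner-filter correction, Stern-Volmer fits per temperature, the
quenching-mechanism call, double-log binding fits per temperature, the
Van't Hoff regression with free-energy consistency diagnostics and force
classification, the synchronous/EEM/CD/SH/ANS conformational probes, and
the foaming/emulsifying indices.  Per-assay failures are isolated and
reported; the run fails only when every assay fails.  Reports are plain
dicts serialisable to JSON, deterministic given (config, seed) — no
timestamps.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import conformation, functional, io, quenching, thermodynamics
from .constants import DEFAULT_DILUTION, DIFFUSION_LIMIT, TAU0, TNB_EXTINCTION
from .datatypes import ThermoResult, ValidationError

__all__ = ["TitrationInput", "LigandInputs", "RunConfig", "run_full_analysis", "consistency_report"]

logger = logging.getLogger(__name__)


class TitrationInput(BaseModel):
    path: str
    temperature: float = Field(gt=0)


class LigandInputs(BaseModel):
    """Input tables for one ligand; every assay is optional."""

    titrations: list[TitrationInput] = Field(default_factory=list)
    synchronous_15: Optional[str] = None
    synchronous_60: Optional[str] = None
    eem: Optional[str] = None
    cd: Optional[str] = None
    sh: Optional[str] = None
    ans: Optional[str] = None
    foam: Optional[str] = None
    emulsion: Optional[str] = None


class RunConfig(BaseModel):
    """Configuration of a full analysis run."""

    model_config = ConfigDict(validate_assignment=True)

    ligands: dict[str, LigandInputs]
    protein_conc_uM: float = Field(default=20.0, gt=0)
    tau0: float = Field(default=TAU0, gt=0)
    diffusion_limit: float = Field(default=DIFFUSION_LIMIT, gt=0)
    extinction: float = Field(default=TNB_EXTINCTION, gt=0)
    dilution: float = Field(default=DEFAULT_DILUTION, gt=0)
    shift_threshold_nm: float = Field(default=1.0, gt=0)
    discrepancy_flag_pct: float = Field(default=5.0, gt=0)
    classifier: str = "literature"
    ans_protein_conc: float = Field(
        default=0.1, gt=0, description="protein factor in the PSH unit convention"
    )
    ans_reference: Optional[str] = Field(
        default=None, description="free-protein ANS CSV for PSH reduction"
    )
    apply_inner_filter: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))


def consistency_report(
    thermo: ThermoResult, ka_by_temp: Mapping[float, float]
) -> list[dict[str, Any]]:
    """Cross-channel thermodynamic diagnostics.

    Compares dG = dH - T dS against dG = -RT ln Ka at each temperature
    (flagging >5% relative disagreement) and checks the sign of the fitted
    dH against the temperature trend of Ka (Ka falling with rising T
    implies an exothermic binding, dH < 0).  With fewer than two
    temperatures there is nothing to diagnose.
    """
    flags: list[dict[str, Any]] = []
    if len(ka_by_temp) < 2:
        return flags
    for t in sorted(ka_by_temp):
        a = thermo.dG_per_T.get(t)
        if a is None:
            continue
        b = thermodynamics.gibbs_from_ka(ka_by_temp[t], t)
        if abs(a - b) > 0.05 * max(abs(a), abs(b)):
            flags.append(
                {
                    "kind": "dG_channel_discrepancy",
                    "temperature": t,
                    "dG_vant_hoff": a,
                    "dG_from_ka": b,
                }
            )
    temps = sorted(ka_by_temp)
    kas = [ka_by_temp[t] for t in temps]
    decreasing = all(b < a for a, b in zip(kas, kas[1:]))
    increasing = all(b > a for a, b in zip(kas, kas[1:]))
    if (decreasing and thermo.dH > 0) or (increasing and thermo.dH < 0):
        flags.append(
            {
                "kind": "dH_sign_vs_ka_trend",
                "dH": thermo.dH,
                "ka_trend": "decreasing" if decreasing else "increasing",
            }
        )
    return flags


def _dump(obj) -> Any:
    return obj.model_dump(by_alias=True, mode="json")


def _summary_table(ligand: str, rows: list[dict[str, Any]]) -> str:
    header = f"{'T':>5} {'Ksv':>10} {'r':>7} {'Ka':>10} {'n':>6} {'r':>7} {'dH':>8} {'dG':>8} {'dS':>8}"
    lines = [f"[{ligand}]", header]
    for row in rows:
        lines.append(
            f"{row['T']:>5g} {row['Ksv']:>10.4g} {row['r_sv']:>7.4f} "
            f"{row['Ka']:>10.4g} {row['n']:>6.3f} {row['r_ka']:>7.4f} "
            f"{row['dH']:>8.2f} {row['dG']:>8.2f} {row['dS']:>8.2f}"
        )
    return "\n".join(lines)


def _analyze_ligand(name: str, inputs: LigandInputs, cfg: RunConfig) -> dict[str, Any]:
    out: dict[str, Any] = {"errors": {}}
    n_ok = 0

    # --- quenching / binding / thermodynamics -----------------------------
    if inputs.titrations:
        try:
            sv_fits, binding, ka_by_temp = [], {}, {}
            pct = None
            for t_in in sorted(inputs.titrations, key=lambda x: x.temperature):
                series = io.read_titration_csv(
                    t_in.path,
                    protein_conc_uM=cfg.protein_conc_uM,
                    temperature=t_in.temperature,
                )
                if cfg.apply_inner_filter:
                    series = quenching.apply_inner_filter(series)
                sv = quenching.stern_volmer_fit(series, tau0=cfg.tau0)
                sv_fits.append(sv)
                logger.info("%s @%g K: Ksv=%.4g (r=%.4f)", name, sv.temperature, sv.Ksv, sv.r)
                bf = quenching.double_log_fit(series)
                binding[t_in.temperature] = bf
                ka_by_temp[t_in.temperature] = bf.Ka
                logger.info("%s @%g K: Ka=%.4g n=%.3f", name, bf.temperature, bf.Ka, bf.n)
                if pct is None:
                    pct = quenching.percent_quenching(series)
            out["quenching"] = {
                "fits": {f"{f.temperature:g}": _dump(f) for f in sv_fits},
                "percent_quenching_at_lowest_T": pct,
            }
            if len(sv_fits) >= 2:
                out["quenching"]["mechanism"] = _dump(
                    quenching.classify_mechanism(sv_fits, cfg.diffusion_limit)
                )
            out["binding"] = {f"{t:g}": _dump(b) for t, b in binding.items()}
            if len(ka_by_temp) >= 2:
                thermo = thermodynamics.VantHoffModel(
                    ka_by_temp,
                    classifier=cfg.classifier,
                    discrepancy_flag_pct=cfg.discrepancy_flag_pct,
                ).fit()
                out["thermodynamics"] = _dump(thermo)
                out["consistency"] = consistency_report(thermo, ka_by_temp)
                out["summary_rows"] = [
                    {
                        "T": f.temperature,
                        "Ksv": f.Ksv,
                        "r_sv": f.r,
                        "Ka": binding[f.temperature].Ka,
                        "n": binding[f.temperature].n,
                        "r_ka": binding[f.temperature].r,
                        "dH": thermo.dH,
                        "dG": thermo.dG_per_T[f.temperature],
                        "dS": thermo.dS,
                    }
                    for f in sv_fits
                ]
            n_ok += 1
        except Exception as e:  # noqa: BLE001 — isolate per-assay failures
            out["errors"]["titrations"] = str(e)
            logger.error("%s titration analysis failed: %s", name, e)

    # --- synchronous fluorescence -----------------------------------------
    for key, dl in (("synchronous_15", 15.0), ("synchronous_60", 60.0)):
        path = getattr(inputs, key)
        if path is None:
            continue
        try:
            series = io.read_spectrum_series_csv(path, delta_lambda=dl)
            out[key] = {
                "rsfq": conformation.rsfq(series),
                "shift": _dump(
                    conformation.peak_shift(series, cfg.shift_threshold_nm)
                ),
            }
            n_ok += 1
        except Exception as e:  # noqa: BLE001
            out["errors"][key] = str(e)

    # --- EEM ---------------------------------------------------------------
    if inputs.eem is not None:
        try:
            peaks = conformation.extract_eem_peaks(io.read_eem_csv(inputs.eem))
            out["eem_peaks"] = [_dump(p) for p in peaks]
            n_ok += 1
        except Exception as e:  # noqa: BLE001
            out["errors"]["eem"] = str(e)

    # --- CD ----------------------------------------------------------------
    if inputs.cd is not None:
        try:
            out["cd"] = _dump(
                conformation.cd_secondary_structure(io.read_cd_csv(inputs.cd))
            )
            n_ok += 1
        except Exception as e:  # noqa: BLE001
            out["errors"]["cd"] = str(e)

    # --- Ellman SH ----------------------------------------------------------
    if inputs.sh is not None:
        try:
            df = pd.read_csv(inputs.sh)
            from .datatypes import SHMeasurement

            vals = [
                conformation.ellman_sh(
                    SHMeasurement(
                        A412=row.A412,
                        protein_mass_conc=row.protein_g_per_L,
                        path_length=getattr(row, "path_cm", 1.0),
                        extinction=cfg.extinction,
                        dilution_factor=getattr(row, "dilution", 1.0),
                    )
                )
                for row in df.itertuples(index=False)
            ]
            out["sh_umol_per_g"] = vals
            n_ok += 1
        except Exception as e:  # noqa: BLE001
            out["errors"]["sh"] = str(e)

    # --- ANS / PSH ----------------------------------------------------------
    if inputs.ans is not None:
        try:
            series = io.read_ans_csv(inputs.ans, protein_conc=cfg.ans_protein_conc)
            fit = conformation.scatchard_fit(series)
            index = conformation.psh(fit, cfg.ans_protein_conc)
            entry = {"fit": _dump(fit), "PSH": index}
            if cfg.ans_reference is not None:
                ref_fit = conformation.scatchard_fit(
                    io.read_ans_csv(cfg.ans_reference, protein_conc=cfg.ans_protein_conc)
                )
                ref = conformation.psh(ref_fit, cfg.ans_protein_conc)
                entry["PSH_reference"] = ref
                entry["reduction_pct"] = conformation.psh_reduction(ref, index)
            out["ans"] = entry
            n_ok += 1
        except Exception as e:  # noqa: BLE001
            out["errors"]["ans"] = str(e)

    # --- functional indices --------------------------------------------------
    if inputs.foam is not None:
        try:
            ms = io.read_foam_csv(inputs.foam)
            fa = [functional.foam_ability(m) for m in ms]
            fs = [functional.foam_stability(m) for m in ms]
            out["foam"] = {
                "FA_pct": functional.replicate_stats(fa),
                "FS_pct": functional.replicate_stats(fs),
            }
            n_ok += 1
        except Exception as e:  # noqa: BLE001
            out["errors"]["foam"] = str(e)
    if inputs.emulsion is not None:
        try:
            ms = io.read_emulsion_csv(inputs.emulsion)
            ea = [functional.emulsifying_ability(m) for m in ms]
            es = [functional.emulsion_stability(m) for m in ms]
            out["emulsion"] = {
                "EA_m2_per_g": functional.replicate_stats(ea),
                "ES_min": functional.replicate_stats(es),
            }
            n_ok += 1
        except Exception as e:  # noqa: BLE001
            out["errors"]["emulsion"] = str(e)

    out["n_assays_ok"] = n_ok
    return out


def run_full_analysis(config: RunConfig, out_path=None) -> dict[str, Any]:
    """Run every configured assay for every ligand; see module docstring.

    Raises ValidationError if no assay inputs are present or all fail.
    Writes the JSON report to ``out_path`` when given.
    """
    if not config.ligands or all(
        not l.titrations
        and all(
            getattr(l, k) is None
            for k in (
                "synchronous_15",
                "synchronous_60",
                "eem",
                "cd",
                "sh",
                "ans",
                "foam",
                "emulsion",
            )
        )
        for l in config.ligands.values()
    ):
        raise ValidationError(
            "no assay inputs configured; expected at least one of: titrations, "
            "synchronous_15/60, eem, cd, sh, ans, foam, emulsion"
        )
    report: dict[str, Any] = {
        "config": {
            "protein_conc_uM": config.protein_conc_uM,
            "tau0_s": config.tau0,
            "diffusion_limit_L_per_mol_s": config.diffusion_limit,
            "classifier": config.classifier,
            "seed": config.seed,
        },
        "ligands": {},
    }
    total_ok = 0
    tables = []
    for name, inputs in config.ligands.items():
        result = _analyze_ligand(name, inputs, config)
        total_ok += result.pop("n_assays_ok")
        rows = result.pop("summary_rows", None)
        if rows:
            tables.append(_summary_table(name, rows))
        report["ligands"][name] = result
    if total_ok == 0:
        raise ValidationError("all assays failed; see per-ligand errors")
    if tables:
        report["summary_table"] = "\n\n".join(tables)
    if out_path is not None:
        Path(out_path).write_text(
            json.dumps(report, indent=2) + "\n", encoding="utf-8"
        )
    return report
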