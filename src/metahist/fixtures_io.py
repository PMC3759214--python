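"""Embedded cohort tables, file I/O and the printed-value reproduction harness.

The study cohort is 12 metastatic prostate cancer patients.  Their
descriptive characteristics (ages, primary volumes, metastasis counts), the
fitted model parameters of the Full model and the derived biological
parameters are fully printed in the source tables and are embedded here as
code-level fixtures, each cell kept in its printed string form so that the
significant digits are known.  The raw per-patient metastasis volume lists
were never published; anything that needs them (per-patient likelihood
values, refits) is out of reach and is replaced by the synthetic generator.

``reproduce_table3`` re-derives the biological parameters from the printed
model parameters and ages, and compares them with the printed values at
printed-precision tolerances.  Patients whose printed inputs are too coarse
for the conversion to be stable (very short W - V, or b1 printed to one or
two significant digits entering a large cancellation in T) are reported but
not gated; the reference patients are 1, 2, 5 and 11.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .core import (
    Constants,
    DEFAULT_CONSTANTS,
    DEFAULT_PRIMARY_VOLUME,
    ModelParams,
    PatientRecord,
    Variant,
    biological_from_model,
    check_constraints,
)

__all__ = [
    "COHORT",
    "FITTED_MODEL_PARAMS",
    "PRINTED_BIOLOGICAL",
    "GATED_PATIENTS",
    "RATIO_TOLERANCES",
    "cohort_records",
    "patient_record",
    "table2_params",
    "reproduce_table3",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_fit_json",
    "write_fit_json",
]

# --- Table 1: descriptive characteristics --------------------------------
# (patient, PSA/Gleason label, surgery?, V, W, S_v cm^3 (None = imputed 20),
#  number of metastases, volume of largest metastasis cm^3)
COHORT = [
    (1, "6.6/9", True, "57.9", "63.7", "27", 36, "28"),
    (2, "NA/7", True, "50.8", "64.6", None, 22, "14"),
    (3, "1365/9", False, "75.7", "80.1", None, 45, "37"),
    (4, "124/9", False, "48.1", "50.7", "19.1", 30, "37"),
    (5, "19.8/5", False, "56.5", "63.2", "26.6", 22, "36"),
    (6, "33/7", False, "60.6", "62.1", None, 24, "19"),
    (7, "856/9", False, "74.3", "75.1", None, 58, "68"),
    (8, "284/8", False, "66.8", "69.6", None, 32, "47"),
    (9, "24/8", False, "70.9", "77.0", None, 27, "28"),
    (10, "60/8", False, "63.6", "71.8", None, 10, "33"),
    (11, "7.3/7", False, "71.8", "72.7", "47", 22, "21"),
    (12, "46/6", False, "57.3", "66.0", None, 18, "35"),
]

# --- Table 2: fitted Full-model parameters (volumes in cm^3) --------------
# (patient, a0, a1 (None for the surgery patients), b0, b1, A, M)
FITTED_MODEL_PARAMS = [
    (1, "3.62e-4", None, "12.00", "3.41", "1.85", "29.74"),
    (2, "3.45e-6", None, "22.50", "0.64", "1.80", "15.09"),
    (3, "2.88e-6", "-5.03", "0.49", "0.01", "2.46", "42.00"),
    (4, "2.37e-3", "-3.89", "1.02", "8.07e-3", "2.34", "41.89"),
    (5, "2.36e-5", "-4.78", "39.67", "0.67", "2.55", "38.18"),
    (6, "1.06", "-2.81", "11.95", "0.80", "2.15", "22.67"),
    (7, "0.56", "-18.00", "12.90", "2.33", "2.95", "76.30"),
    (8, "0.64", "-4.33", "8.41", "2.03", "4.63", "52.67"),
    (9, "8.81e-5", "-8.39", "2.55", "0.15", "2.49", "30.68"),
    (10, "1.14", "-1.16", "43.05", "2.20", "10.34", "35.78"),
    (11, "1.18e-3", "-11.52", "31.47", "6.25e-2", "2.73", "22.45"),
    (12, "0.53", "-3.73", "12.92", "0.35", "1.24", "40.76"),
]

# --- Table 3: printed biological parameters of the Full model -------------
# (patient, gamma0, gamma1, gamma1/gamma0, beta0, beta1, rho, theta, T,
#  age at earliest inception) -- all printed strings; beta1 None for the
#  surgery patients.
PRINTED_BIOLOGICAL = [
    (1, "1.047", "3.684", "3.5", "9.1", None, "0.08", "4.2e-5", "55.3", "55.3"),
    (2, "0.044", "1.543", "35.3", "0.5", None, "1.0", "3.1e-7", "2.2", "3.3"),
    (3, "0.120", "4.971", "39.7", "1.0", "-4.6e4", "16.3", "3.4e-7", "53.1", "54.1"),
    (4, "0.066", "8.362", "126.4", "0.5", "-7.1", "14.8", "2.9e-4", "4.5", "6.5"),
    (5, "0.054", "3.238", "59.5", "0.5", "-1.6e3", "0.46", "2.7e-6", "6.8", "7.8"),
    (6, "0.930", "13.864", "14.8", "9.4", "-1.7", "0.090", "0.10", "58.1", "58.2"),
    (7, "4.680", "25.958", "5.5", "34.1", "-198.4", "0.016", "7.6e-2", "73.6", "73"),
    (8, "1.940", "8.034", "4.1", "18.9", "-30.7", "0.061", "6.6e-2", "65.6", "65.6"),
    (9, "0.210", "3.570", "16.9", "2.0", "-1.1e4", "1.9", "9.3e-6", "59.0", "59.5"),
    (10, "0.140", "2.805", "19.6", "2.7", "-0.1", "0.16", "6.0e-2", "55.0", "55.4"),
    (11, "0.048", "24.142", "503.7", "0.6", "-10.9", "0.66", "1.0e-4", "27.8", "28.8"),
    (12, "0.066", "2.412", "36.6", "0.4", "-0.09", "1.17", "7.8e-2", "4.3", "6.6"),
]

#: Reference patients gated in the printed-value reproduction; the others are
#: reported with a rounding-amplification flag.
GATED_PATIENTS = (1, 2, 5, 11)

#: Per-patient relative tolerance on the growth-acceleration ratio
#: gamma1/gamma0 for the gated comparison (tighter for patient 11, whose
#: printed value carries four significant digits).
RATIO_TOLERANCES = {11: 0.005, 2: 0.02}

_QUANTITIES = ("gamma0", "gamma1", "ratio", "beta0", "rho", "theta", "T")


def _half_ulp(printed: str) -> float:
    """Half a unit in the last printed digit of a decimal/scientific literal."""
    s = printed.strip().lower().lstrip("+-")
    if "e" in s:
        mant, exp = s.split("e")
        scale = 10.0 ** int(exp)
    else:
        mant, scale = s, 1.0
    if "." in mant:
        places = len(mant.split(".")[1])
    else:
        places = 0
    return 0.5 * 10.0 ** (-places) * scale


def cohort_records() -> List[PatientRecord]:
    """Embedded cohort as PatientRecords (metastasis volume lists are not in
    the printed record, so ``met_volumes`` is empty)."""
    out = []
    for pid, _label, surgery, V, W, Sv, _n, _largest in COHORT:
        out.append(
            PatientRecord(
                patient_id=f"p{pid}",
                V=float(V),
                W=float(W),
                S_v=float(Sv) if Sv is not None else DEFAULT_PRIMARY_VOLUME,
                surgery=surgery,
                S_v_imputed=Sv is None,
            )
        )
    return out


def patient_record(pid: int) -> PatientRecord:
    return cohort_records()[pid - 1]


def patient_meta(pid: int) -> dict:
    row = COHORT[pid - 1]
    return {
        "patient": pid,
        "psa_gleason": row[1],
        "surgery": row[2],
        "n_metastases": row[6],
        "largest_met_cm3": float(row[7]),
    }


def table2_params(pid: int, constants: Constants = DEFAULT_CONSTANTS) -> ModelParams:
    """Fitted model parameters of patient ``pid`` as sizes (cell counts).

    The two surgery patients carry the surgery variant (no a1); everyone
    else the full variant.
    """
    row = FITTED_MODEL_PARAMS[pid - 1]
    _, a0, a1, b0, b1, A, M = row
    surgery = COHORT[pid - 1][2]
    variant = Variant.SURGERY if surgery else Variant.FULL
    return ModelParams(
        A=float(A) / constants.c,
        M=float(M) / constants.c,
        a0=float(a0),
        a1=float(a1) if a1 is not None else None,
        b0=float(b0),
        b1=float(b1),
        variant=variant,
    )


def reproduce_table3(
    constants: Constants = DEFAULT_CONSTANTS,
    rel_tol: float = 0.02,
    T_abs_tol: float = 0.2,
) -> pd.DataFrame:
    """Recompute the biological parameters from the printed fit and ages.

    Returns one row per patient and quantity with the computed value, the
    printed value, the relative deviation and a ``passed`` flag.  A quantity
    passes when it agrees within ``rel_tol`` relative error or within half a
    unit in the last printed digit, whichever is looser (the tables print
    some rates to a single significant figure); the onset age ``T`` is
    compared at ``T_abs_tol`` years absolute because it is obtained by
    subtracting two numbers of order V.  Only the reference patients
    (``GATED_PATIENTS``) are gated; the others are flagged.  The printed
    beta1 column is reported but never gated: it does not follow from the
    printed model parameters (see the package methods note).
    """
    rows = []
    for pid in range(1, 13):
        rec = patient_record(pid)
        params = table2_params(pid, constants)
        bio = biological_from_model(params, rec, constants)
        printed = PRINTED_BIOLOGICAL[pid - 1]
        computed = {
            "gamma0": bio.gamma0,
            "gamma1": bio.gamma1,
            "ratio": bio.gamma1 / bio.gamma0,
            "beta0": bio.beta0,
            "rho": bio.rho,
            "theta": bio.theta,
            "T": bio.T,
        }
        printed_map = {
            "gamma0": printed[1],
            "gamma1": printed[2],
            "ratio": printed[3],
            "beta0": printed[4],
            "rho": printed[6],
            "theta": printed[7],
            "T": printed[8],
        }
        gated = pid in GATED_PATIENTS
        for q in _QUANTITIES:
            ref = float(printed_map[q])
            val = computed[q]
            dev = abs(val - ref) / abs(ref)
            if q == "T":
                ok = abs(val - ref) <= T_abs_tol
            elif q == "ratio":
                ok = dev <= RATIO_TOLERANCES.get(pid, rel_tol)
            else:
                tol_abs = max(rel_tol * abs(ref), _half_ulp(printed_map[q]))
                ok = abs(val - ref) <= tol_abs
            rows.append(
                {
                    "patient": pid,
                    "quantity": q,
                    "computed": val,
                    "printed": ref,
                    "rel_dev": dev,
                    "gated": gated,
                    "passed": ok,
                }
            )
        # beta1 reported, never gated (not derivable from the printed fit for
        # the systemic-treatment patients)
        if printed[5] is not None and bio.beta1 is not None:
            rows.append(
                {
                    "patient": pid,
                    "quantity": "beta1",
                    "computed": bio.beta1,
                    "printed": float(printed[5]),
                    "rel_dev": abs(bio.beta1 - float(printed[5])) / abs(float(printed[5])),
                    "gated": False,
                    "passed": True,
                }
            )
    return pd.DataFrame(rows)


def table2_feasibility(constants: Constants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Constraint report for every printed fit against the printed ages."""
    rows = []
    for pid in range(1, 13):
        rec = patient_record(pid)
        params = table2_params(pid, constants)
        rep = check_constraints(params, rec, constants)
        rows.append(
            {
                "patient": pid,
                "ordering": rep.ordering,
                "above_threshold": rep.above_threshold,
                "onset_positive": rep.onset_positive,
                "passed": rep.passed,
                "M_cm3": params.M * constants.c,
                "largest_met_cm3": patient_meta(pid)["largest_met_cm3"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV / JSON I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "patient_id",
    "age_treatment_years",
    "age_survey_years",
    "primary_volume_cm3",
    "surgery",
    "met_volumes_cm3",
]


class CohortFormatError(ValueError):
    """Malformed cohort CSV."""


def read_cohort_csv(
    path, constants: Constants = DEFAULT_CONSTANTS
) -> List[PatientRecord]:
    """Read patient records from CSV.

    Columns: patient_id, age_treatment_years, age_survey_years,
    primary_volume_cm3 (blank imputes 20 cm^3 and sets the imputed flag),
    surgery (0/1), met_volumes_cm3 (semicolon-separated, each >= m).
    Malformed rows are reported with their line number.
    """
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortFormatError(f"{path}: empty file")
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise CohortFormatError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                V = float(row["age_treatment_years"])
                W = float(row["age_survey_years"])
                if W <= V:
                    raise ValueError(
                        "survey age W must exceed treatment age V (cohort criterion W > V)"
                    )
                sv_raw = (row["primary_volume_cm3"] or "").strip()
                imputed = sv_raw == ""
                S_v = DEFAULT_PRIMARY_VOLUME if imputed else float(sv_raw)
                vols_raw = (row["met_volumes_cm3"] or "").strip()
                vols = [float(v) for v in vols_raw.split(";") if v.strip()] if vols_raw else []
                rec = PatientRecord(
                    patient_id=row["patient_id"],
                    V=V,
                    W=W,
                    S_v=S_v,
                    surgery=str(row["surgery"]).strip() in ("1", "true", "True"),
                    met_volumes=tuple(vols),
                    S_v_imputed=imputed,
                )
                rec.validate_volumes(constants)
            except (ValueError, KeyError) as exc:
                raise CohortFormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_cohort_csv(path, records: Sequence[PatientRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    repr(r.V),
                    repr(r.W),
                    "" if r.S_v_imputed else repr(r.S_v),
                    int(r.surgery),
                    ";".join(repr(v) for v in r.met_volumes),
                ]
            )


def write_fit_json(path, results) -> None:
    """Serialize one FitResult or a list of them to JSON."""
    from .inference import FitResult  # local import to avoid a cycle

    if isinstance(results, FitResult):
        results = [results]
    payload = [r.to_dict() for r in results]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_fit_json(path) -> list:
    with open(path) as fh:
        return json.load(fh)
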