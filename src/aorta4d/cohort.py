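"""Synthetic study cohorts built on the inverse size-WSS mechanism.

Generates per-subject tables shaped like a two-group pediatric aortopathy
study (a connective-tissue-disease group with root and proximal-descending
dilatation versus healthy controls): BSA, landmark Z-scores and diameters,
percent size change along the isthmus-to-proximal-descending segment,
flow-pattern grades, and a proximal-descending WSS tied to local diameter by
the Poiseuille fixed-flow-rate scaling tau ~ d^-3.  Used to exercise the
statistics module with known effect directions at realistic sample sizes.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import NormativeModel, default_normative_model

#: per-landmark (patient_mean, patient_sd, control_mean, control_sd) Z-scores
#: emulating a dilated-root / dilated-pDAo aortopathy cohort
DEFAULT_Z_EFFECTS = {
    "Root": (3.56, 1.45, 0.49, 0.78),
    "STJ": (1.70, 1.28, -0.34, 0.77),
    "midAAo": (0.21, 0.95, -0.54, 0.64),
    "distal_arch": (0.14, 0.90, -0.23, 0.66),
    "isthmus": (0.96, 0.94, 0.43, 0.49),
    "pDAo": (2.02, 1.60, 0.56, 0.66),
}

#: probability of vortex grades {0,1,2} in the proximal descending aorta
DEFAULT_VORTEX_P = {"patient": (0.44, 0.30, 0.26), "control": (0.905, 0.075, 0.02)}


def simulate_cohort(n_patients: int = 25, n_controls: int = 21, seed: int = 0,
                    normative: NormativeModel | None = None,
                    wss_ref_pa: float = 0.87, wss_noise_sd: float = 0.12
                    ) -> pd.DataFrame:
    """Per-subject GroupTable with a built-in inverse diameter-WSS relation.

    The proximal-descending WSS is generated from the subject's local
    diameter through the fixed-flow-rate wall-shear scaling
    tau = tau_ref * (d_ref / d)^3, multiplied by lognormal measurement
    noise; larger vessels therefore carry lower WSS by construction.
    """
    rng = np.random.default_rng(seed)
    model = normative if normative is not None else default_normative_model()

    rows = []
    n_total = n_patients + n_controls
    d_ref = None
    for i in range(n_total):
        patient = i < n_patients
        group = "patient" if patient else "control"
        bsa = float(np.clip(rng.normal(1.78 if patient else 1.61,
                                       0.36 if patient else 0.25), 0.8, 2.4))
        row = {"subject_id": f"S{i:03d}", "group": group, "bsa": bsa,
               "age": float(np.clip(rng.normal(15.8, 3.5), 6, 25)),
               "sex": rng.choice(["F", "M"])}
        diam = {}
        for lm, (mp, sp, mc, sc) in DEFAULT_Z_EFFECTS.items():
            z = rng.normal(mp, sp) if patient else rng.normal(mc, sc)
            d = model.mean_diameter_mm(lm, bsa) + z * model.sd_mm(lm)
            row[f"z_{lm}"] = z
            diam[lm] = d
        row["pct_change_isthmus_pdao"] = (
            abs(diam["isthmus"] - diam["pDAo"]) / diam["isthmus"] * 100.0)

        if d_ref is None:
            d_ref = model.mean_diameter_mm("pDAo", 1.61) + 0.56 * model.sd_mm("pDAo")
        tau = wss_ref_pa * (d_ref / diam["pDAo"]) ** 3
        row["wss_inner_pDAo"] = float(tau * rng.lognormal(0.0, wss_noise_sd))

        p = DEFAULT_VORTEX_P[group]
        row["grade_vortex_pDAo"] = int(rng.choice([0, 1, 2], p=p))
        row["subgroup"] = ("control" if not patient else
                           ("pDAo_dilated" if row["z_pDAo"] >= 2.0 else "pDAo_nondilated"))
        rows.append(row)
    return pd.DataFrame(rows)
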