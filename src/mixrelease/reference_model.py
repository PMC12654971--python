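"""Published coefficient values of the reference release model.

These are the reported MCP-selected QIF coefficients for the glipizide
study, kept as data for side-by-side comparison with refitted models.  The
source prints the intercept with opposite signs in the model equation
(-4.27112) and in the rounded coefficient table (+4.2711).  Evaluating raw
component products with the full-precision equation coefficients but the
POSITIVE intercept reproduces the published 45 candidate release profiles
to a median absolute error of about 0.2 release points, while the printed
equation sign misses them all by a constant ~8.5 (twice the intercept) and
the rounded table coefficients are too coarse: the equation's intercept
sign is a typo, and no hidden term transformation is involved.  All three
variants are stored; ``RECONCILED_COEFFICIENTS`` is the corrected one.

The package still refits the model to the study data for its own pipeline -
the published values serve as reference data and cross-checks.
"""

from __future__ import annotations

__all__ = ["EQUATION_COEFFICIENTS", "TABLE_COEFFICIENTS", "printed_model_coefficients"]

#: Full-precision coefficients as printed in the model equation.
EQUATION_COEFFICIENTS = {
    "intercept": -4.27112,
    "X24": -0.01113,
    "X25": -0.00974,
    "X35": -0.61399,
    "X134": -0.00165,
    "X135": 0.01076,
    "X12345": 0.00005,
    "X3t": 0.02473,
    "X5t": -0.00049,
    "t2": -0.21985,
    "t": 9.08641,
}

#: Rounded coefficients as printed in the inference table (note the
#: positive intercept, conflicting with the equation's sign).
TABLE_COEFFICIENTS = {
    "intercept": 4.2711,
    "X24": -0.0111,
    "X25": -0.0097,
    "X35": -0.6140,
    "X134": -0.0017,
    "X135": 0.0108,
    "X12345": 0.0001,
    "X3t": 0.0247,
    "X5t": -0.0005,
    "t2": -0.2199,
    "t": 9.0864,
}

#: Full-precision coefficients with the intercept sign corrected (the
#: variant that reproduces the published candidate predictions).
RECONCILED_COEFFICIENTS = {**EQUATION_COEFFICIENTS, "intercept": 4.27112}

#: Term labels of the published selected model (intercept excluded).
SELECTED_TERMS = [lab for lab in EQUATION_COEFFICIENTS if lab != "intercept"]


def printed_model_coefficients(source: str = "reconciled") -> dict:
    """The published coefficient map.

    ``source``: 'reconciled' (sign-corrected, recommended), 'equation'
    (as printed in the model equation) or 'table' (rounded table values).
    """
    variants = {
        "reconciled": RECONCILED_COEFFICIENTS,
        "equation": EQUATION_COEFFICIENTS,
        "table": TABLE_COEFFICIENTS,
    }
    if source not in variants:
        raise ValueError("source must be 'reconciled', 'equation' or 'table'")
    return dict(variants[source])
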