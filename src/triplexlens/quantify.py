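"""qPCR-based quantification utilities: ddCt, ChIP double normalization,
CLIP RNA recovery.

Input is a tidy Ct table (one row per well) with columns:

``sample, condition, gene, is_reference, fraction, antibody, ct``

* ``is_reference`` — True on rows of the reference gene (ddCt);
* ``fraction`` — fraction of material used for the row (e.g. 0.01 for a 1%
  input aliquot, 0.20 for a 20% IP), used for the material correction;
* ``antibody`` — "input", "IgG", the target antibody name, or "none".

Amplification efficiency defaults to 2.0 (classic ddCt; one cycle = one
doubling) and is exposed as a parameter everywhere.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from triplexlens.errors import DataError, ValidationError

REQUIRED_COLUMNS = (
    "sample",
    "condition",
    "gene",
    "is_reference",
    "fraction",
    "antibody",
    "ct",
)


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"Ct table missing columns: {missing}")
    ct = pd.to_numeric(table["ct"], errors="coerce")
    if ct.isna().any() or not np.isfinite(ct).all() or (ct <= 0).any():
        raise DataError("all Ct values must be finite and > 0")
    out = table.copy()
    out["ct"] = ct
    return out


def ddct_expression(
    table: pd.DataFrame,
    target: str,
    reference: str = "Atp5bp",
    control_condition: str = "ctrl-Fc",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Relative expression of ``target`` by the ddCt method.

    Per sample: dCt = Ct_target − Ct_reference; ddCt = dCt − mean dCt of the
    control condition; fold change = efficiency^−ddCt.  The control
    condition therefore averages to a geometric mean of 1.0.
    """
    if efficiency <= 1.0:
        raise ValidationError("efficiency must be > 1")
    table = _validate_table(table)
    tgt = table[(table["gene"] == target) & (~table["is_reference"])]
    ref = table[(table["gene"] == reference) & (table["is_reference"])]
    if ref.empty:
        raise DataError(f"reference gene {reference!r} not found in table")
    if tgt.empty:
        raise DataError(f"target gene {target!r} not found in table")
    ref_ct = ref.set_index("sample")["ct"]

    rows = []
    for _, row in tgt.iterrows():
        if row["sample"] not in ref_ct.index:
            raise DataError(
                f"sample {row['sample']!r} has no reference-gene Ct"
            )
        rows.append(
            {
                "sample": row["sample"],
                "condition": row["condition"],
                "dct": row["ct"] - float(ref_ct[row["sample"]]),
            }
        )
    result = pd.DataFrame(rows)
    control = result[result["condition"] == control_condition]
    if control.empty:
        raise DataError(
            f"control condition {control_condition!r} absent from table"
        )
    control_mean = float(control["dct"].mean())
    result["ddct"] = result["dct"] - control_mean
    result["fold_change"] = efficiency ** (-result["ddct"])
    return result[["sample", "condition", "dct", "ddct", "fold_change"]]


def _recovery(
    ct_ip: float,
    ct_input: float,
    f_ip: float,
    f_input: float,
    efficiency: float,
) -> float:
    """Percent recovery vs input with material-fraction correction.

    The input Ct is first adjusted to the IP's material amount
    (Ct_input_adj = Ct_input − log2(f_ip / f_input) cycles at efficiency 2),
    then recovery = efficiency^(Ct_input_adj − Ct_ip) · 100%.
    """
    if f_ip <= 0 or f_input <= 0:
        raise DataError("material fractions must be > 0")
    adjust = math.log(f_ip / f_input, efficiency)
    ct_input_adj = ct_input - adjust
    return 100.0 * efficiency ** (ct_input_adj - ct_ip)


def chip_fold_enrichment(
    table: pd.DataFrame,
    target_antibody: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """ChIP-qPCR double normalization: input recovery, then IgG.

    Per (condition, gene): recovery of the target antibody and of IgG are
    computed against the fraction-corrected input; fold enrichment is their
    ratio.  A zero/absent IgG recovery is reported as ``inf`` with the
    ``igg_zero`` flag set rather than raising.
    """
    table = _validate_table(table)
    rows = []
    for (condition, gene), grp in table.groupby(["condition", "gene"], sort=True):
        by_ab = {ab: sub for ab, sub in grp.groupby("antibody")}
        if "input" not in by_ab:
            raise DataError(
                f"no input row for condition={condition!r}, gene={gene!r}"
            )
        if target_antibody not in by_ab:
            raise DataError(
                f"no {target_antibody!r} row for condition={condition!r}, "
                f"gene={gene!r}"
            )
        inp = by_ab["input"].iloc[0]

        def rec(sub: pd.DataFrame) -> float:
            r = sub.iloc[0]
            return _recovery(
                float(r["ct"]),
                float(inp["ct"]),
                float(r["fraction"]),
                float(inp["fraction"]),
                efficiency,
            )

        recovery_target = rec(by_ab[target_antibody])
        igg_zero = "IgG" not in by_ab
        recovery_igg = None if igg_zero else rec(by_ab["IgG"])
        if igg_zero or recovery_igg == 0.0:
            fold = math.inf
            igg_zero = True
        else:
            fold = recovery_target / recovery_igg
        rows.append(
            {
                "condition": condition,
                "gene": gene,
                "recovery_target_pct": recovery_target,
                "recovery_igg_pct": recovery_igg,
                "fold_enrichment": fold,
                "igg_zero": igg_zero,
            }
        )
    return pd.DataFrame(rows)


def clip_recovery(
    table: pd.DataFrame,
    target_antibody: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """CLIP RNA recovery: pulled-down RNA relative to total RNA.

    Per (condition, gene): recovery fraction of the target-antibody IP
    against the fraction-adjusted total-RNA ("input") row.  IgG rows are
    reported alongside as the noise floor when present.
    """
    table = _validate_table(table)
    rows = []
    for (condition, gene), grp in table.groupby(["condition", "gene"], sort=True):
        by_ab = {ab: sub for ab, sub in grp.groupby("antibody")}
        if "input" not in by_ab:
            raise DataError(
                f"no total-RNA (input) row for condition={condition!r}, "
                f"gene={gene!r}"
            )
        inp = by_ab["input"].iloc[0]

        def rec(sub: pd.DataFrame) -> float:
            r = sub.iloc[0]
            return (
                _recovery(
                    float(r["ct"]),
                    float(inp["ct"]),
                    float(r["fraction"]),
                    float(inp["fraction"]),
                    efficiency,
                )
                / 100.0
            )

        if target_antibody not in by_ab:
            raise DataError(
                f"no {target_antibody!r} row for condition={condition!r}, "
                f"gene={gene!r}"
            )
        rows.append(
            {
                "condition": condition,
                "gene": gene,
                "antibody": target_antibody,
                "recovery": rec(by_ab[target_antibody]),
                "igg_recovery": rec(by_ab["IgG"]) if "IgG" in by_ab else None,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "REQUIRED_COLUMNS",
    "ddct_expression",
    "chip_fold_enrichment",
    "clip_recovery",
]
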