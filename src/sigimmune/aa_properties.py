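"""Charge and Kyte-Doolittle hydrophobicity deltas of amino-acid substitutions.

Charge assignment: Asp and Glu are negative (-1); Lys, Arg and His are
positive (+1); the remaining 15 standard residues are neutral.  The
hydrophobicity difference follows the convention KD(wild-type) - KD(mutant),
with a positive difference labelled "increase" — note this direction is
literal to its original description and can be swapped with
``label_convention``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import AssociationResult, cuzick_trend

#: Integer charge per residue: D/E negative, K/R/H positive (His taken as
#: fully protonated), everything else neutral.
CHARGE: dict[str, int] = {
    **{aa: 0 for aa in "ACFGILMNPQSTVWY"},
    "D": -1, "E": -1,
    "K": +1, "R": +1, "H": +1,
}

#: Kyte-Doolittle hydropathy index per residue.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

STANDARD_AAS = frozenset(CHARGE)


def charge(aa: str) -> int:
    """Integer charge of a standard residue (stop or nonstandard is an error)."""
    try:
        return CHARGE[aa]
    except KeyError:
        raise ValueError(f"not a standard amino acid: {aa!r}") from None


def kd(aa: str) -> float:
    """Kyte-Doolittle hydropathy of a standard residue."""
    try:
        return KYTE_DOOLITTLE[aa]
    except KeyError:
        raise ValueError(f"not a standard amino acid: {aa!r}") from None


def _sign_class(delta: float) -> str:
    if delta > 0:
        return "increase"
    if delta < 0:
        return "decrease"
    return "none"


@dataclass(frozen=True)
class PropertyDelta:
    """Charge and hydrophobicity change of one amino-acid substitution."""

    charge_delta: int  # mutant - wild-type, in [-2, 2]
    charge_class: str
    hydropathy_delta: float  # wild-type - mutant by default convention
    hydropathy_class: str


def charge_delta_class(wt_aa: str, mut_aa: str) -> tuple[int, str]:
    """Charge change of a substitution: delta = charge(mut) - charge(wt)."""
    if wt_aa == mut_aa:
        raise ValueError("wild-type and mutant residues are identical")
    delta = charge(mut_aa) - charge(wt_aa)
    return delta, _sign_class(delta)


def hydrophobicity_delta_class(
    wt_aa: str, mut_aa: str, label_convention: str = "wt_minus_mut"
) -> tuple[float, str]:
    """Hydropathy change of a substitution.

    With the default convention the difference is KD(wt) - KD(mut) and a
    positive difference is labelled "increase" (literal convention; the
    mutant is then actually *less* hydrophobic).  ``label_convention
    ="mut_minus_wt"`` swaps the direction.
    """
    if label_convention not in ("wt_minus_mut", "mut_minus_wt"):
        raise ValueError(f"unknown label convention {label_convention!r}")
    delta = kd(wt_aa) - kd(mut_aa)
    if label_convention == "mut_minus_wt":
        delta = -delta
    return delta, _sign_class(delta)


def property_delta(
    wt_aa: str, mut_aa: str, label_convention: str = "wt_minus_mut"
) -> PropertyDelta:
    cdelta, cclass = charge_delta_class(wt_aa, mut_aa)
    hdelta, hclass = hydrophobicity_delta_class(wt_aa, mut_aa, label_convention)
    return PropertyDelta(cdelta, cclass, hdelta, hclass)


PROPERTY_COLUMNS = [
    "charge_increase", "charge_decrease", "charge_none",
    "hydro_increase", "hydro_decrease", "hydro_none",
]


def count_property_changes(
    annotations: pd.DataFrame,
    per_sample: bool = False,
    attribution_col: str = "assigned_signature",
    label_convention: str = "wt_minus_mut",
) -> pd.DataFrame:
    """Count charge/hydrophobicity change classes per signature.

    Only missense records are counted; every missense record must carry a
    signature attribution.  With ``per_sample`` the table is indexed by
    (sample_id, signature).  Within each property the class counts partition
    the missense set.
    """
    miss = annotations[annotations["consequence"] == "missense"].copy()
    if attribution_col in miss.columns:
        missing = miss[miss[attribution_col].isna()]
        if len(missing):
            keys = missing[["sample_id", "gene_id", "pos_1based_cds"]].values.tolist()
            raise ValueError(f"missense records without attribution: {keys[:10]}")
    else:
        raise KeyError(f"annotations lack {attribution_col!r}")
    if miss.empty:
        index = (
            pd.MultiIndex.from_arrays([[], []], names=["sample_id", "signature"])
            if per_sample
            else pd.Index([], name="signature")
        )
        return pd.DataFrame(0, index=index, columns=PROPERTY_COLUMNS, dtype=int)

    deltas = [
        property_delta(w, m, label_convention)
        for w, m in zip(miss["wt_aa"], miss["mut_aa"])
    ]
    miss["charge_class"] = ["charge_" + d.charge_class for d in deltas]
    miss["hydro_class"] = ["hydro_" + d.hydropathy_class for d in deltas]
    keys = (["sample_id", attribution_col] if per_sample else [attribution_col])
    c = miss.groupby(keys)["charge_class"].value_counts().unstack(fill_value=0)
    h = miss.groupby(keys)["hydro_class"].value_counts().unstack(fill_value=0)
    out = c.join(h, how="outer").fillna(0).astype(int)
    out = out.reindex(columns=PROPERTY_COLUMNS, fill_value=0)
    out.index = out.index.rename(
        ["sample_id", "signature"] if per_sample else "signature"
    )
    return out


def per_sample_charge_increase(
    annotations: pd.DataFrame,
    attribution_col: str = "assigned_signature",
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Samples x signatures table of charge-increasing missense counts."""
    tab = count_property_changes(annotations, per_sample=True,
                                 attribution_col=attribution_col)
    wide = tab["charge_increase"].unstack(fill_value=0)
    if samples is not None:
        wide = wide.reindex(index=samples, fill_value=0)
    return wide


def charge_increase_trend(
    per_sample_counts: pd.DataFrame,
    infiltrate: pd.Series,
    signature_id: str = "ALL",
    exclude: tuple[str, ...] = (),
) -> AssociationResult:
    """Trend of per-sample charge-increasing counts across ordered infiltrate.

    ``signature_id="ALL"`` sums across signatures (optionally excluding some,
    e.g. to test whether a trend survives removal of the dominant signature);
    otherwise a single signature's counts are tested.  Cuzick's nonparametric
    trend test is used.
    """
    counts = per_sample_counts.drop(columns=list(exclude), errors="ignore")
    if signature_id == "ALL":
        values = counts.sum(axis=1)
    else:
        if signature_id not in counts.columns:
            raise KeyError(f"signature {signature_id!r} not in counts table")
        values = counts[signature_id]
    values = values.reindex(infiltrate.index)
    if values.isna().any():
        raise ValueError("infiltrate labels for samples missing from counts")
    if (values == 0).all():
        raise ValueError(
            "all charge-increase counts are zero (nothing left to test"
            + (f" after excluding {list(exclude)}" if exclude else "")
            + ")"
        )
    if infiltrate.nunique() < 2:
        raise ValueError("fewer than 2 occupied infiltrate levels")
    return cuzick_trend(values.values, np.asarray(infiltrate.values))
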