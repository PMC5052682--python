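"""Trinucleotide-context classification, signature refitting and per-mutation attribution.

Somatic single-base substitutions are classified into the standard 96 classes
(pyrimidine-normalized substitution plus 5' and 3' flanking bases).  Per-sample
exposures to a fixed signature catalog are refit by non-negative least squares,
each mutation is attributed to a signature by its posterior under the fitted
mixture, and samples are grouped by dominant-signature proportion or by total
mutational burden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = frozenset("CT")

#: Canonical class order: alphabetical by "X[R>A]Y" label.
CONTEXT_CLASSES: list[str] = sorted(
    f"{five}[{ref}>{alt}]{three}"
    for ref in "CT"
    for alt in "ACGT"
    if alt != ref
    for five in "ACGT"
    for three in "ACGT"
)
CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(CONTEXT_CLASSES)}

#: Signatures the source analyses excluded for having too few carriers.
DEFAULT_EXCLUDED_SIGNATURES = frozenset({"6", "17", "20", "26", "30"})


class ContextError(ValueError):
    """A substitution that cannot be assigned a 96-class context."""


def trinucleotide_context(sequence: str, pos_1based: int, ref: str, alt: str) -> str:
    """Return the canonical 96-class label "X[R>A]Y" for a substitution.

    Purine references are reverse-complemented (ref, alt and both flanks
    complemented, flanks swapped) so the mutated base is always a pyrimidine.

    Parameters
    ----------
    sequence : the contig / CDS sequence (uppercase ACGTN).
    pos_1based : 1-based position of the mutated base; must have both flanks
        inside the sequence.
    ref, alt : reference and alternate base on the given strand.
    """
    seq = sequence.upper()
    ref, alt = ref.upper(), alt.upper()
    if not 1 < pos_1based < len(seq):
        raise ContextError(
            f"position {pos_1based} has no flanking bases within the sequence "
            f"(length {len(seq)})"
        )
    if ref == alt:
        raise ContextError(f"ref and alt are both {ref!r}")
    found = seq[pos_1based - 1]
    if found != ref:
        raise ContextError(
            f"reference mismatch at position {pos_1based}: sequence has "
            f"{found!r}, record says {ref!r}"
        )
    five, three = seq[pos_1based - 2], seq[pos_1based]
    for base in (five, three, ref, alt):
        if base not in "ACGT":
            raise ContextError(
                f"non-ACGT base {base!r} at/around position {pos_1based}"
            )
    if ref not in PYRIMIDINES:
        five, three = COMPLEMENT[three], COMPLEMENT[five]
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{five}[{ref}>{alt}]{three}"


def classify_mutations(mutations: pd.DataFrame, cds: dict[str, str]) -> pd.DataFrame:
    """Add a ``context`` column to a mutation table.

    Records whose flanks contain N (or fall on a sequence edge) are dropped
    with a logged warning; a ref/sequence mismatch is an error.
    """
    contexts: list[str | None] = []
    n_skipped = 0
    for gene, pos, ref, alt in zip(
        mutations["gene_id"], mutations["pos_1based_cds"],
        mutations["ref"], mutations["alt"],
    ):
        if gene not in cds:
            raise KeyError(f"gene {gene!r} not present in the reference")
        try:
            contexts.append(trinucleotide_context(cds[gene], int(pos), ref, alt))
        except ContextError as exc:
            if "mismatch" in str(exc):
                raise
            contexts.append(None)
            n_skipped += 1
    if n_skipped:
        logger.warning("skipped %d unclassifiable records", n_skipped)
    out = mutations.copy()
    out["context"] = contexts
    return out[out["context"].notna()].reset_index(drop=True)


def build_spectrum(
    mutations: pd.DataFrame, per_sample: bool = False
) -> pd.Series | pd.DataFrame:
    """Count mutations per 96-class (pooled Series, or samples x 96 DataFrame)."""
    if "context" not in mutations.columns:
        raise KeyError("mutation table lacks a 'context' column; classify first")
    if mutations.empty:
        logger.warning("empty mutation table: all-zero spectrum")
        if per_sample:
            return pd.DataFrame(columns=CONTEXT_CLASSES, dtype=int)
        return pd.Series(0, index=CONTEXT_CLASSES, dtype=int)
    if per_sample:
        counts = (
            mutations.groupby("sample_id")["context"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=CONTEXT_CLASSES, fill_value=0)
        )
        counts.columns.name = None
        return counts.astype(int)
    return (
        mutations["context"].value_counts().reindex(CONTEXT_CLASSES, fill_value=0)
    ).astype(int)


def validate_catalog(catalog: pd.DataFrame, atol: float = 1e-9) -> None:
    """Check a 96 x S signature catalog: canonical index, columns sum to 1."""
    if list(catalog.index) != CONTEXT_CLASSES:
        raise ValueError("catalog index must be the 96 canonical class labels")
    if (catalog.values < 0).any():
        raise ValueError("catalog contains negative probabilities")
    sums = catalog.sum(axis=0)
    bad = sums[(sums - 1.0).abs() > atol]
    if len(bad):
        raise ValueError(f"catalog columns do not sum to 1: {list(bad.index)}")


@dataclass
class ExposureVector:
    """Fitted per-sample signature exposures.

    ``counts`` are the NNLS-fitted attributed mutation numbers per signature
    (same scale as the input spectrum); ``proportions`` are the normalized
    weights (sum to 1 when any mutation was fitted).
    """

    signatures: list[str]
    counts: np.ndarray
    residual: float
    sample_id: str | None = None
    proportions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        total = float(self.counts.sum())
        self.proportions = (
            self.counts / total if total > 0 else np.zeros_like(self.counts)
        )


def fit_exposures(spectrum, catalog: pd.DataFrame, sample_id: str | None = None) -> ExposureVector:
    """Refit signature exposures for one spectrum by non-negative least squares.

    Minimizes ``||spectrum - catalog @ w||`` subject to ``w >= 0`` on the raw
    counts; normalized weights are reported alongside the fitted counts.
    """
    validate_catalog(catalog)
    s = np.asarray(
        spectrum.reindex(CONTEXT_CLASSES).values
        if isinstance(spectrum, pd.Series)
        else spectrum,
        dtype=float,
    )
    if s.shape != (96,):
        raise ValueError("spectrum must have 96 entries")
    if (s < 0).any():
        raise ValueError("spectrum has negative counts")
    if s.sum() == 0:
        raise ValueError("no mutations to fit")
    w, rnorm = nnls(catalog.values, s)
    return ExposureVector(list(catalog.columns), w, float(rnorm), sample_id)


def fit_exposures_per_sample(
    spectra: pd.DataFrame, catalog: pd.DataFrame
) -> pd.DataFrame:
    """NNLS refit for every row of a samples x 96 spectrum table.

    Returns a samples x signatures DataFrame of fitted counts with a
    ``residual`` column appended.
    """
    rows = {}
    for sample, spec in spectra.iterrows():
        ev = fit_exposures(spec, catalog, sample_id=str(sample))
        rows[sample] = np.append(ev.counts, ev.residual)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(catalog.columns) + ["residual"]
    )
    out.index.name = "sample_id"
    return out


def attribute_mutations(
    mutations: pd.DataFrame,
    catalog: pd.DataFrame,
    exposures: pd.DataFrame,
) -> pd.DataFrame:
    """Assign each classified mutation to a signature by maximum posterior.

    For a mutation of class ``c`` in sample ``j`` the posterior over
    signatures is ``p(s) ∝ exposure_j(s) * catalog(c, s)``.  Assignment is the
    argmax; exact ties go to the lowest catalog column index and are flagged.
    A class with zero probability under every exposed signature is attributed
    uniformly over the exposed signatures and flagged unresolved.
    """
    validate_catalog(catalog)
    sig_ids = list(catalog.columns)
    cat = catalog.values  # 96 x S
    out = mutations.copy()
    n = len(out)
    assigned = np.empty(n, dtype=object)
    posterior = np.empty(n)
    margin = np.empty(n)
    tie = np.zeros(n, dtype=bool)
    unresolved = np.zeros(n, dtype=bool)

    class_idx = out["context"].map(CLASS_INDEX).values.astype(int)
    for sample, idx in out.groupby("sample_id").indices.items():
        if sample not in exposures.index:
            raise KeyError(f"no fitted exposures for sample {sample!r}")
        w = exposures.loc[sample, sig_ids].values.astype(float)
        if w.sum() <= 0:
            raise ValueError(f"sample {sample!r} has all-zero exposures")
        post = cat * w[None, :]  # 96 x S, unnormalized
        rowsum = post.sum(axis=1)
        zero_rows = rowsum == 0
        if zero_rows.any():
            exposed = (w > 0).astype(float)
            post[zero_rows] = exposed / exposed.sum()
            rowsum = post.sum(axis=1)
        post = post / rowsum[:, None]
        best = np.argmax(post, axis=1)
        srt = np.sort(post, axis=1)
        ci = class_idx[idx]
        assigned[idx] = np.asarray(sig_ids, dtype=object)[best[ci]]
        posterior[idx] = post[ci, best[ci]]
        margin[idx] = srt[ci, -1] - (srt[ci, -2] if post.shape[1] > 1 else 0.0)
        tie[idx] = margin[idx] <= 1e-12
        unresolved[idx] = zero_rows[ci]

    out["assigned_signature"] = assigned
    out["posterior"] = posterior
    out["margin"] = margin
    out["tie"] = tie
    out["unresolved"] = unresolved
    return out


def signature_proportions(
    attributions: pd.DataFrame,
    signature_ids: list[str] | None = None,
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample attributed mutation counts and proportions per signature.

    Returns ``(counts, proportions)``; proportions of a zero-mutation sample
    are all zero.  ``samples`` may list samples absent from the attribution
    table (reported with all-zero rows).
    """
    counts = (
        attributions.groupby("sample_id")["assigned_signature"]
        .value_counts()
        .unstack(fill_value=0)
    )
    if signature_ids is not None:
        counts = counts.reindex(columns=signature_ids, fill_value=0)
    if samples is not None:
        counts = counts.reindex(index=samples, fill_value=0)
    counts.columns.name = None
    totals = counts.sum(axis=1)
    props = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return counts.astype(int), props


def dominant_signature_groups(
    proportions: pd.DataFrame,
    signature_id: str,
    hi: float = 0.50,
    lo: float = 0.20,
    min_n: int = 15,
) -> tuple[pd.Series, bool]:
    """Group samples by the proportion of one signature.

    HIGH when proportion >= ``hi``, LOW when < ``lo``, otherwise EXCLUDED.
    The contrast is valid only when both groups hold at least ``min_n`` cases.
    """
    if not 0 <= lo < hi <= 1:
        raise ValueError(f"thresholds must satisfy 0 <= lo < hi <= 1, got {lo}, {hi}")
    p = proportions[signature_id]
    labels = pd.Series("EXCLUDED", index=proportions.index, name="group")
    labels[p >= hi] = "HIGH"
    labels[p < lo] = "LOW"
    valid = (labels == "HIGH").sum() >= min_n and (labels == "LOW").sum() >= min_n
    return labels, bool(valid)


def burden_extreme_groups(total_counts: pd.Series, frac: float = 0.20) -> pd.Series:
    """Label the top/bottom ``frac`` of samples by total substitution count.

    Ranking is over the whole pooled input (no stratification); ties are
    broken by stable input order.
    """
    n = len(total_counts)
    if n < 5:
        raise ValueError("need at least 5 samples for burden grouping")
    if not 0 < frac <= 0.5:
        raise ValueError("frac must be in (0, 0.5]")
    k = int(np.floor(frac * n))
    values = total_counts.values
    if np.all(values == values[0]):
        logger.warning("all burden counts equal; groups follow input order")
    order_asc = np.argsort(values, kind="stable")
    labels = pd.Series("MIDDLE", index=total_counts.index, name="group")
    labels.iloc[order_asc[:k]] = "BOTTOM"
    labels.iloc[order_asc[n - k:]] = "TOP"
    return labels
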