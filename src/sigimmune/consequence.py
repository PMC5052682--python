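"""Codon consequences, mutant peptide windows and the strong-binder decision rule.

A coding substitution is translated to its amino-acid consequence with the
standard genetic code.  For missense changes a peptide window of up to 17
residues centred on the mutant position is cut from the mutant protein, all
contiguous 9-mers containing the mutant residue are enumerated, and a
substitution is flagged as a candidate neo-epitope when any 9-mer is predicted
to bind any queried MHC class I allele with EC50 strictly below a threshold
(default 50 nM).  The binding model itself is pluggable: any object mapping
(peptide, allele) to an EC50 in nM can be used.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from typing import Protocol

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_STOPS = set(standard_dna_table.stop_codons)

#: The ten most prevalent Caucasian HLA-A2 class I alleles queried by default.
DEFAULT_HLA_A2_ALLELES: tuple[str, ...] = tuple(
    f"HLA-A2:{x:02d}" for x in (1, 2, 3, 6, 11, 12, 16, 17, 19, 50)
)

STRONG_BINDER_THRESHOLD_NM = 50.0


def _translate_codon(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    try:
        return standard_dna_table.forward_table[codon]
    except KeyError:
        raise ValueError(f"cannot translate codon {codon!r}") from None


@dataclass(frozen=True)
class AAChangeAnnotation:
    """Codon-level consequence of one coding substitution."""

    gene_id: str
    codon_index: int  # 1-based; equals the protein position
    wt_aa: str
    mut_aa: str
    consequence: str  # silent | missense | nonsense | stop_loss | start_loss

    @property
    def protein_position(self) -> int:
        return self.codon_index


def annotate_coding_consequence(
    cds: str, pos_1based: int, ref: str, alt: str, gene_id: str = ""
) -> AAChangeAnnotation:
    """Translate one substitution on a CDS to its amino-acid consequence."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    if not 1 <= pos_1based <= len(cds):
        raise ValueError(f"position {pos_1based} outside CDS of length {len(cds)}")
    if cds[pos_1based - 1] != ref.upper():
        raise ValueError(
            f"reference mismatch at CDS position {pos_1based}: "
            f"{cds[pos_1based - 1]!r} != {ref!r}"
        )
    codon_index = (pos_1based - 1) // 3 + 1
    start = 3 * (codon_index - 1)
    codon = cds[start:start + 3]
    offset = (pos_1based - 1) % 3
    mut_codon = codon[:offset] + alt.upper() + codon[offset + 1:]
    wt_aa = _translate_codon(codon)
    mut_aa = _translate_codon(mut_codon)
    if wt_aa == mut_aa:
        consequence = "silent"
    elif mut_aa == "*":
        consequence = "nonsense"
    elif wt_aa == "*":
        consequence = "stop_loss"
    elif codon_index == 1 and wt_aa == "M":
        consequence = "start_loss"
    else:
        consequence = "missense"
    return AAChangeAnnotation(gene_id, codon_index, wt_aa, mut_aa, consequence)


def translate_cds(cds: str) -> str:
    """Whole-CDS translation (stop rendered as '*')."""
    return str(Seq(cds).translate())


def annotate_mutations(mutations: pd.DataFrame, cds: dict[str, str]) -> pd.DataFrame:
    """Annotate every record of a mutation table with its codon consequence."""
    records = []
    for row in mutations.itertuples(index=False):
        ann = annotate_coding_consequence(
            cds[row.gene_id], int(row.pos_1based_cds), row.ref, row.alt, row.gene_id
        )
        records.append((ann.codon_index, ann.wt_aa, ann.mut_aa, ann.consequence))
    out = mutations.copy()
    out[["codon_index", "wt_aa", "mut_aa", "consequence"]] = pd.DataFrame(
        records, index=out.index,
        columns=["codon_index", "wt_aa", "mut_aa", "consequence"],
    )
    return out


class WindowRejected(ValueError):
    """A peptide window could not be formed (protein shorter than 9 aa)."""


@dataclass(frozen=True)
class PeptideWindow:
    """A mutant peptide window with the 1-based offset of the mutant residue."""

    peptide: str
    mutant_offset: int

    def __post_init__(self) -> None:
        if not 1 <= self.mutant_offset <= len(self.peptide):
            raise ValueError("mutant offset outside the window")


def extract_peptide_window(
    protein: str, mutant_pos: int, flank: int = 8
) -> PeptideWindow:
    """Cut the (up to) 17-mer window around a mutant residue.

    The window spans protein positions ``max(1, p-flank)..min(L, p+flank)``,
    clamped at the protein ends; proteins shorter than 9 residues are
    rejected.  A terminal '*' is not part of the protein.
    """
    protein = protein.rstrip("*")
    length = len(protein)
    if length < 9:
        raise WindowRejected(f"protein of {length} aa is too short for a 9-mer")
    if not 1 <= mutant_pos <= length:
        raise ValueError(f"mutant position {mutant_pos} outside protein of {length} aa")
    if protein[mutant_pos - 1] == "*":
        raise ValueError("mutant residue is a stop")
    lo = max(1, mutant_pos - flank)
    hi = min(length, mutant_pos + flank)
    return PeptideWindow(protein[lo - 1:hi], mutant_pos - lo + 1)


def enumerate_9mers(window: PeptideWindow) -> list[str]:
    """All contiguous 9-mers of the window containing the mutant residue.

    A full 17-mer with the mutant centred yields exactly 9 peptides; a
    boundary window of length ``m`` (9..16) yields at most ``m - 8``.
    """
    m, off = len(window.peptide), window.mutant_offset
    if m < 9:
        raise ValueError("window shorter than 9 residues")
    first = max(1, off - 8)
    last = min(m - 8, off)
    return [window.peptide[s - 1:s + 8] for s in range(first, last + 1)]


class EC50Predictor(Protocol):
    """Anything that predicts a binding EC50 in nM for (peptide, allele)."""

    def predict(self, peptide: str, allele: str) -> float: ...


class ConstantPredictor:
    """Stub predictor returning a fixed EC50 for every query."""

    def __init__(self, ec50_nM: float = 500.0):
        self.ec50_nM = float(ec50_nM)

    def predict(self, peptide: str, allele: str) -> float:
        return self.ec50_nM


class HashPredictor:
    """Deterministic pseudo-predictor for tests and synthetic cohorts.

    Each (peptide, allele) pair is hashed to a uniform variate; with
    probability ``p_strong`` the EC50 is uniform on (0, 50) nM, otherwise
    log-uniform on [50, 50000) nM.  Independent of any biology by design.
    """

    def __init__(self, p_strong: float = 0.01, salt: str = ""):
        if not 0 <= p_strong <= 1:
            raise ValueError("p_strong must be in [0, 1]")
        self.p_strong = p_strong
        self.salt = salt

    def predict(self, peptide: str, allele: str) -> float:
        digest = hashlib.md5(
            f"{self.salt}|{peptide}|{allele}".encode()
        ).digest()
        u = int.from_bytes(digest[:8], "big") / 2**64
        v = int.from_bytes(digest[8:16], "big") / 2**64
        if u < self.p_strong:
            return 50.0 * max(v, 1e-9)
        return 50.0 * 10 ** (3.0 * v)


class TablePredictor:
    """Predictor backed by a TSV of columns peptide, allele, ec50_nM."""

    def __init__(self, table: pd.DataFrame):
        self._lut = {
            (p, a): float(e)
            for p, a, e in zip(table["peptide"], table["allele"], table["ec50_nM"])
        }

    @classmethod
    def from_tsv(cls, path) -> "TablePredictor":
        return cls(pd.read_csv(path, sep="\t"))

    def predict(self, peptide: str, allele: str) -> float:
        try:
            return self._lut[(peptide, allele)]
        except KeyError:
            raise KeyError(f"no prediction for ({peptide!r}, {allele!r})") from None


@dataclass
class BinderCall:
    """Strong-binder decision for one substitution's candidate peptides."""

    strong_binder: bool
    best_ec50_nM: float
    best_peptide: str | None
    best_allele: str | None
    n_predictions: int
    n_failures: int


def call_neoepitope(
    peptides: list[str],
    predictor: EC50Predictor,
    alleles: tuple[str, ...] = DEFAULT_HLA_A2_ALLELES,
    threshold_nM: float = STRONG_BINDER_THRESHOLD_NM,
) -> BinderCall:
    """OR over all peptide x allele predictions strictly below the threshold.

    A prediction failure is logged, treated as a non-binder and counted.
    """
    if not alleles:
        raise ValueError("no alleles given")
    best = math.inf
    best_pep = best_allele = None
    n_pred = n_fail = 0
    for pep in peptides:
        for allele in alleles:
            n_pred += 1
            try:
                ec50 = float(predictor.predict(pep, allele))
            except Exception as exc:  # predictor is third-party code
                logger.warning("predictor failed on (%s, %s): %s", pep, allele, exc)
                n_fail += 1
                continue
            if ec50 < best:
                best, best_pep, best_allele = ec50, pep, allele
    return BinderCall(
        strong_binder=best < threshold_nM,
        best_ec50_nM=best,
        best_peptide=best_pep,
        best_allele=best_allele,
        n_predictions=n_pred,
        n_failures=n_fail,
    )


def annotate_cohort(
    mutations: pd.DataFrame,
    cds: dict[str, str],
    predictor: EC50Predictor | None = None,
    alleles: tuple[str, ...] = DEFAULT_HLA_A2_ALLELES,
    threshold_nM: float = STRONG_BINDER_THRESHOLD_NM,
    flank: int = 8,
) -> pd.DataFrame:
    """Consequence-annotate a mutation table and, for missense records,
    attach the peptide window, 9-mer count and strong-binder flag.

    Silent and terminating (nonsense / stop-loss / start-loss) records carry
    no window and a null binder flag.  Proteins shorter than 9 aa are
    rejected and logged with a reason code.
    """
    ann = annotate_mutations(mutations, cds)
    proteins = {g: translate_cds(s) for g, s in cds.items()}
    windows: list[str | None] = []
    offsets: list[float] = []
    n9: list[float] = []
    binder: list[bool | None] = []
    for row in ann.itertuples(index=False):
        if row.consequence != "missense":
            windows.append(None)
            offsets.append(np.nan)
            n9.append(np.nan)
            binder.append(None)
            continue
        wt_protein = proteins[row.gene_id].rstrip("*")
        mut_protein = (
            wt_protein[: row.codon_index - 1]
            + row.mut_aa
            + wt_protein[row.codon_index:]
        )
        try:
            win = extract_peptide_window(mut_protein, int(row.codon_index), flank)
        except WindowRejected as exc:
            logger.warning("window rejected (%s %s): %s", row.gene_id, row.codon_index, exc)
            windows.append(None)
            offsets.append(np.nan)
            n9.append(np.nan)
            binder.append(None)
            continue
        mers = enumerate_9mers(win)
        windows.append(win.peptide)
        offsets.append(win.mutant_offset)
        n9.append(len(mers))
        if predictor is None:
            binder.append(None)
        else:
            call = call_neoepitope(mers, predictor, alleles, threshold_nM)
            binder.append(call.strong_binder)
    ann["window"] = windows
    ann["window_offset"] = offsets
    ann["n_9mers"] = n9
    ann["strong_binder"] = binder
    return ann


def neoepitope_fraction_by_signature(
    annotations: pd.DataFrame, attribution_col: str = "assigned_signature"
) -> pd.Series:
    """Fraction of attributed missense substitutions flagged strong binders.

    The denominator per signature is its missense substitutions with a binder
    call; a zero denominator yields NaN (undefined), never 0.
    """
    miss = annotations[
        (annotations["consequence"] == "missense")
        & annotations["strong_binder"].notna()
    ]
    if attribution_col not in annotations.columns:
        raise KeyError(f"annotations lack {attribution_col!r}")
    grouped = miss.groupby(attribution_col)["strong_binder"]
    frac = grouped.apply(lambda s: s.astype(bool).mean() if len(s) else np.nan)
    frac.name = "neoepitope_fraction"
    return frac
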