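"""Triploid allelic-constitution classification and per-locus hDNA frequency.

At a screened SSR locus the female parent carries alleles a/b and the male
parent c (or c/d). A captured hDNA tract makes the triploid maternally
heterozygous, so the six clean constitutions are abc, abd (hDNA present) and
aac, bbc, aad, bbd (absent). Anything else — no paternal allele, off-parent
alleles, both paternal alleles — is ambiguous and treated as missing, so the
frequency denominator contains only the six clean classes:

    HF = N_ab / (N_ab + N_aa + N_bb)
"""

from __future__ import annotations

from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import MarkerLocus, MarkerPanel, ValidationError
from .simulate import TriploidGenotypeTable

CONSTITUTIONS = ("abc", "abd", "aac", "bbc", "aad", "bbd", "ambiguous", "missing")
_PRESENT = frozenset({"abc", "abd"})
_ABSENT = frozenset({"aac", "bbc", "aad", "bbd"})


class HdnaCall(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    MISSING = "missing"


def _match(size: int, targets: tuple[int, ...], tol: int) -> int | None:
    """Index of the target fragment size matching within +/- tol bins, else None."""
    for i, t in enumerate(targets):
        if abs(size - t) <= tol:
            return i
    return None


def classify_genotype(
    cell: tuple[int, ...] | None,
    locus: MarkerLocus,
    size_tolerance: int = 0,
) -> str:
    """Classify one triploid cell into an allelic constitution label.

    ``size_tolerance`` (fragment-size bins, default 0 = exact match)
    accommodates electropherogram jitter. Dosage is ignored: SSR peaks report
    allele presence, not copy number.
    """
    if cell is None or len(cell) == 0:
        return "missing"
    maternal_seen = set()
    paternal_seen = set()
    for size in cell:
        mi = _match(size, locus.maternal_alleles, size_tolerance)
        pi = _match(size, locus.paternal_alleles, size_tolerance)
        if mi is not None:
            maternal_seen.add(mi)
        elif pi is not None:
            paternal_seen.add(pi)
        else:
            return "ambiguous"  # off-parent allele
    if len(paternal_seen) != 1:
        return "ambiguous"  # no paternal allele, or both
    pat = "c" if paternal_seen == {0} else "d"
    if maternal_seen == {0, 1}:
        return "ab" + pat
    if maternal_seen == {0}:
        return "aa" + pat
    if maternal_seen == {1}:
        return "bb" + pat
    return "ambiguous"  # no maternal allele observed


def classify_table(
    table: TriploidGenotypeTable,
    panel: MarkerPanel,
    size_tolerance: int = 0,
) -> pd.DataFrame:
    """Constitution label per (individual, locus); columns ordered as the panel."""
    panel_ids = set(panel.marker_ids)
    extra = [m for m in table.marker_ids if m not in panel_ids]
    if extra:
        raise ValidationError(f"genotype table loci not in panel: {extra}")
    cols = {}
    for mid in table.marker_ids:
        locus = panel[mid]
        cols[mid] = [
            classify_genotype(table.cell(ind, mid), locus, size_tolerance)
            for ind in table.individuals
        ]
    return pd.DataFrame(cols, index=table.individuals, columns=table.marker_ids)


def call_hdna(
    table: TriploidGenotypeTable,
    panel: MarkerPanel,
    size_tolerance: int = 0,
) -> pd.DataFrame:
    """hDNA call matrix: 'present' / 'absent' / 'missing' per (individual, locus).

    present iff constitution in {abc, abd}; ambiguous collapses to missing.
    """
    cons = classify_table(table, panel, size_tolerance)
    return constitutions_to_calls(cons)


def constitutions_to_calls(constitutions: pd.DataFrame) -> pd.DataFrame:
    def to_call(label: str) -> str:
        if label in _PRESENT:
            return HdnaCall.PRESENT.value
        if label in _ABSENT:
            return HdnaCall.ABSENT.value
        return HdnaCall.MISSING.value

    return constitutions.map(to_call)


def hdna_frequency(
    constitutions: pd.DataFrame,
    panel: MarkerPanel,
) -> pd.DataFrame:
    """Per-locus hDNA frequency table.

    Columns: marker_id, chrom, pos_bp, N_ab, N_aa, N_bb, n_missing, HF.
    HF = N_ab / (N_ab + N_aa + N_bb); NaN (flagged, not an error) when the
    denominator is zero. Ambiguous and missing calls are excluded from all
    three counts.
    """
    rows = []
    for mid in constitutions.columns:
        locus = panel[mid]
        col = constitutions[mid]
        n_ab = int(col.isin(["abc", "abd"]).sum())
        n_aa = int(col.isin(["aac", "aad"]).sum())
        n_bb = int(col.isin(["bbc", "bbd"]).sum())
        n_missing = len(col) - n_ab - n_aa - n_bb
        denom = n_ab + n_aa + n_bb
        rows.append(
            {
                "marker_id": mid,
                "chrom": locus.chrom,
                "pos_bp": locus.pos_bp,
                "N_ab": n_ab,
                "N_aa": n_aa,
                "N_bb": n_bb,
                "n_missing": n_missing,
                "HF": n_ab / denom if denom > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def write_hdna_frequency(hf: pd.DataFrame, path: str | Path) -> None:
    out = hf.copy()
    out["pos_bp"] = out["pos_bp"] + 1  # 1-based in files
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_hdna_frequency(path: str | Path) -> pd.DataFrame:
    hf = pd.read_csv(path, sep="\t")
    hf["pos_bp"] = hf["pos_bp"] - 1
    return hf
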