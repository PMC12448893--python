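"""In-silico proteolytic digestion and iBAQ computation.

iBAQ (intensity-based absolute quantification) divides a protein's summed
MS intensity by the number of tryptic peptides the instrument could in
principle observe, giving a quantity proportional to molar amount and hence
comparable between proteins of different length.  The peptide count comes
from an in-silico digest of the protein sequence.

Two cleavage rules are supported:

``trypsin_p``
    Cleave C-terminal of every K and R, including before proline
    (Trypsin/P convention).
``argc_propionyl``
    Cleave C-terminal of R only.  This models tryptic digestion of
    propionylated histones: chemical derivatization blocks free lysines, so
    trypsin produces Arg-C-like peptides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

CLEAVAGE_RESIDUES = {
    "trypsin_p": frozenset("KR"),
    "argc_propionyl": frozenset("R"),
}


@dataclass(frozen=True)
class DigestParams:
    """Digestion settings.

    Parameters
    ----------
    rule : {"trypsin_p", "argc_propionyl"}
        Cleavage specificity.
    missed_cleavages : int
        Maximum number of internal cleavage sites a reported peptide may
        retain.  0 (fully cleaved) is the iBAQ counting convention; search
        engines typically allow 3 (tryptic) or 5 (propionylated histones).
    min_length, max_length : int
        Inclusive peptide-length window for observable-peptide counting.
        The 6-30 default is the standard iBAQ observability window.
    """

    rule: str = "trypsin_p"
    missed_cleavages: int = 0
    min_length: int = 6
    max_length: int = 30

    def __post_init__(self) -> None:
        if self.rule not in CLEAVAGE_RESIDUES:
            raise ValueError(f"unknown cleavage rule: {self.rule!r}")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.min_length < 1 or self.min_length > self.max_length:
            raise ValueError("length window requires 1 <= min <= max")


@dataclass(frozen=True)
class Peptide:
    """A digest product with 1-based inclusive coordinates."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    bad = set(seq) - _AA_SET
    if bad:
        raise ValueError(f"illegal residue(s) in sequence: {sorted(bad)}")
    return seq


def cleavage_sites(sequence: str, rule: str) -> list[int]:
    """0-based indices i such that the bond after ``sequence[i]`` is cut."""
    residues = CLEAVAGE_RESIDUES[rule]
    n = len(sequence)
    # C-terminal residue ends the chain regardless; it is not a cleavage site.
    return [i for i in range(n - 1) if sequence[i] in residues]


def digest_protein(sequence: str, params: DigestParams) -> list[Peptide]:
    """Digest ``sequence``, returning peptides with positions.

    With ``missed_cleavages = m``, the products are every run of up to
    ``m + 1`` adjacent fully-cleaved fragments.  Identical spans are
    reported once; peptides are ordered by start position then length.
    """
    seq = _validate_sequence(sequence)
    sites = cleavage_sites(seq, params.rule)
    # Fragment boundaries as 0-based half-open [b, e) intervals.
    bounds = [0] + [i + 1 for i in sites] + [len(seq)]
    peptides: list[Peptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for m in range(params.missed_cleavages + 1):
            j = i + m + 1
            if j > n_frag:
                break
            b, e = bounds[i], bounds[j]
            peptides.append(Peptide(seq[b:e], b + 1, e, m))
    return peptides


def count_observable_peptides(sequence: str, params: DigestParams | None = None) -> int:
    """Number of distinct digest peptides within the length window.

    This is the iBAQ denominator.  May return 0 (e.g. a short protein with
    no fragment inside the window).
    """
    if params is None:
        params = DigestParams()
    distinct = {
        pep.sequence
        for pep in digest_protein(sequence, params)
        if params.min_length <= len(pep.sequence) <= params.max_length
    }
    return len(distinct)


@dataclass
class IbaqTable:
    """Per-protein iBAQ values.

    ``frame`` is indexed by protein ID with one ``ibaq_<sample>`` column per
    sample, plus ``observable_peptides`` and ``ibaq_mean`` (mean over
    detected treatment-group replicates; NaN when the protein was never
    detected or has no observable peptides).
    """

    frame: pd.DataFrame
    samples: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def ibaq_mean(self, protein_id: str) -> float:
        return float(self.frame.at[protein_id, "ibaq_mean"])

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.frame.index


def compute_ibaq_table(
    table,
    fasta: Mapping[str, str],
    design,
    params: DigestParams | None = None,
    which: str = "intensity",
    aggregate: str = "mean",
) -> IbaqTable:
    """Compute iBAQ from a protein-groups table.

    Parameters
    ----------
    table : ProteinGroupsTable
    fasta : mapping protein ID -> sequence
        Proteins absent from the mapping are skipped with a warning.
    design : SampleDesign
        ``ibaq_mean`` averages treatment-group samples only; zero
        intensities count as missing, not abundance, and are excluded.
    params : DigestParams, optional
        Defaults to fully-cleaved Trypsin/P, length 6-30.
    which : {"intensity", "lfq"}
        Which intensity columns feed the calculation (raw by default).
    aggregate : {"mean", "sum"}
        How detected treatment replicates are combined into ``ibaq_mean``.
    """
    if params is None:
        params = DigestParams()
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    intens = table.intensities(which)
    samples = list(intens.columns)
    treatment_samples = [s for s in samples if design.groups[s] == design.treatment]

    rows = {}
    skipped: list[str] = []
    for pid, values in intens.iterrows():
        if pid not in fasta:
            skipped.append(pid)
            continue
        count = count_observable_peptides(fasta[pid], params)
        row = {"observable_peptides": count}
        if count == 0:
            warnings.warn(
                f"{pid}: no observable peptides in window "
                f"{params.min_length}-{params.max_length}; iBAQ undefined",
                stacklevel=2,
            )
            for s in samples:
                row[f"ibaq_{s}"] = np.nan
            row["ibaq_mean"] = np.nan
        else:
            for s in samples:
                row[f"ibaq_{s}"] = values[s] / count
            detected = [
                values[s] / count for s in treatment_samples if values[s] > 0
            ]
            if detected:
                agg = np.mean if aggregate == "mean" else np.sum
                row["ibaq_mean"] = float(agg(detected))
            else:
                row["ibaq_mean"] = np.nan
        rows[pid] = row
    if skipped:
        warnings.warn(
            f"{len(skipped)} protein(s) without a sequence skipped", stacklevel=2
        )
    frame = pd.DataFrame.from_dict(rows, orient="index")
    return IbaqTable(frame=frame, samples=samples, skipped=skipped)


def enumerate_digests_bruteforce(
    sequence: str, rule: str, missed_cleavages: int
) -> set[tuple[str, int, int]]:
    """Exhaustive digestion oracle: enumerate contiguous subsequences.

    A span [i, j) is a valid digest product iff its left and right
    boundaries are termini or cleavage points and it contains at most
    ``missed_cleavages`` internal cleavage sites.  Quadratic in sequence
    length; for testing only.
    """
    seq = _validate_sequence(sequence)
    residues = CLEAVAGE_RESIDUES[rule]
    n = len(seq)
    cut_after = [i for i in range(n - 1) if seq[i] in residues]
    boundary = {0, n} | {i + 1 for i in cut_after}
    out: set[tuple[str, int, int]] = set()
    for b in sorted(boundary):
        for e in sorted(boundary):
            if e <= b:
                continue
            internal = sum(1 for i in cut_after if b <= i < e - 1)
            if internal <= missed_cleavages:
                out.add((seq[b:e], b + 1, e))
    return out
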