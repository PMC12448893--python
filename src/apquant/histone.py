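"""Acetyl-site-level quantification from derivatized histone peptides.

Propionylation blocks tryptic cleavage at lysines, so digestion of
derivatized histones yields Arg-C-like tail peptides whose lysines carry
either an acetyl (endogenous) or a propionyl (chemical) group.  Records
from a modified-peptide table are mapped onto mature-histone coordinates
(initiator Met removed, so the familiar "H3 K18" style labels apply) and
aggregated by acetyl-site combination: a peptide acetylated at K18 and K23
contributes to the single key ``"H3 K18ac+K23ac"`` and never to the
individual sites, which keeps combinations from being double-counted.

The change statistics reuse the label-free machinery (median
normalization, down-shifted imputation, Student's t with permutation FDR)
on the site-combination table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import SampleDesign
from .stats import (
    ImputeParams,
    LogIntensityMatrix,
    TestParams,
    filter_min_valid,
    impute_gaussian_downshift,
    median_normalize,
    permutation_fdr,
)

#: Synthetic mature-histone reference segments (Met-clipped numbering).
#: These cover the N-terminal tail regions the quantified peptides map to;
#: stand-ins for full UniProt entries, adequate for coordinate checks.
SYNTHETIC_HISTONE_REFERENCES: dict[str, str] = {
    "H3": "ARTKQTAR" + "KSTGGKAPR" + "KQLATKAAR" + "KSAPATGGVKKPHR",
    "H4": "SGR" + "GKGGKGLGKGGAKR" + "HRKVLRDNIQGITKPAIR",
    "H2B": "PEPAKSAPAPK" + "KGSKKAVTKAQKK" + "DGKKR",
}

MOD_TYPES = ("acetyl", "propionyl")


@dataclass
class ModifiedPeptideRecord:
    """One quantified (modified) peptide.

    ``start`` is 1-based in mature-histone numbering; ``modifications``
    is a list of (1-based residue offset within the peptide, type).
    """

    protein: str
    sequence: str
    start: int
    modifications: list[tuple[int, str]]
    intensity: dict[str, float]

    def __post_init__(self) -> None:
        seen: dict[int, str] = {}
        for offset, kind in self.modifications:
            if not 1 <= offset <= len(self.sequence):
                raise ValueError(
                    f"modification offset {offset} outside peptide "
                    f"{self.sequence!r}"
                )
            if kind not in MOD_TYPES:
                raise ValueError(f"unknown modification type {kind!r}")
            if offset in seen and seen[offset] != kind:
                raise ValueError(
                    f"residue {offset}: acetyl and propionyl are mutually exclusive"
                )
            seen[offset] = kind

    @property
    def acetyl_positions(self) -> tuple[int, ...]:
        """Acetylated residues in mature-protein coordinates, sorted."""
        return tuple(
            sorted(self.start + off - 1 for off, kind in self.modifications
                   if kind == "acetyl")
        )

    def site_key(self) -> str | None:
        """``"H3 K18ac+K23ac"``-style key, or None if unacetylated."""
        positions = self.acetyl_positions
        if not positions:
            return None
        return f"{self.protein} " + "+".join(f"K{p}ac" for p in positions)


def read_modified_peptides(path: str | Path) -> list[ModifiedPeptideRecord]:
    """Parse a modified-peptide TSV.

    Columns: ``protein``, ``sequence``, ``start``, ``modifications``
    (semicolon-joined ``offset:type``, may be empty) and one
    ``Intensity <sample>`` column per sample.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein", "sequence", "start", "modifications"}
    if not required <= set(frame.columns):
        raise ValueError(f"modified-peptide table needs columns {sorted(required)}")
    samples = [c[len("Intensity "):] for c in frame.columns if c.startswith("Intensity ")]
    if not samples:
        raise ValueError("no 'Intensity <sample>' columns found")
    records = []
    for _, row in frame.iterrows():
        mods = []
        if row["modifications"].strip():
            for token in row["modifications"].split(";"):
                pos, kind = token.strip().split(":")
                mods.append((int(pos), kind))
        records.append(
            ModifiedPeptideRecord(
                protein=row["protein"],
                sequence=row["sequence"].upper(),
                start=int(row["start"]),
                modifications=mods,
                intensity={s: float(row[f"Intensity {s}"]) for s in samples},
            )
        )
    return records


def records_from_frame(frame: pd.DataFrame) -> list[ModifiedPeptideRecord]:
    """Build records from an in-memory simulator table (same columns as
    ``read_modified_peptides`` expects on disk)."""
    samples = [c[len("Intensity "):] for c in frame.columns if c.startswith("Intensity ")]
    records = []
    for _, row in frame.iterrows():
        mods = []
        if str(row["modifications"]).strip():
            for token in str(row["modifications"]).split(";"):
                pos, kind = token.strip().split(":")
                mods.append((int(pos), kind))
        records.append(
            ModifiedPeptideRecord(
                protein=row["protein"],
                sequence=str(row["sequence"]).upper(),
                start=int(row["start"]),
                modifications=mods,
                intensity={s: float(row[f"Intensity {s}"]) for s in samples},
            )
        )
    return records


@dataclass
class SiteQuantTable:
    """Site-combination x sample intensity table."""

    frame: pd.DataFrame  # index: site-combination key; columns: samples
    rejected: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.columns)


def map_peptides_to_sites(
    records: Iterable[ModifiedPeptideRecord],
    references: Mapping[str, str] | None = None,
) -> SiteQuantTable:
    """Aggregate modified-peptide records into acetyl-site combinations.

    A record is rejected (with a log entry) when its sequence disagrees
    with the reference at the stated position or its acetylated residues
    are not lysines.  Unacetylated (fully propionylated) records carry no
    site information and are ignored.  Intensities for the same key are
    summed across records (charge states, duplicates).
    """
    if references is None:
        references = SYNTHETIC_HISTONE_REFERENCES
    sums: dict[str, dict[str, float]] = {}
    rejected: list[str] = []
    for rec in records:
        ref = references.get(rec.protein)
        label = f"{rec.protein}:{rec.start}:{rec.sequence}"
        if ref is not None:
            segment = ref[rec.start - 1 : rec.start - 1 + len(rec.sequence)]
            if segment != rec.sequence:
                rejected.append(f"{label}: sequence mismatch with reference")
                continue
        elif references:
            rejected.append(f"{label}: unknown histone {rec.protein!r}")
            continue
        if any(
            rec.sequence[off - 1] != "K"
            for off, kind in rec.modifications
            if kind == "acetyl"
        ):
            rejected.append(f"{label}: acetyl on non-lysine residue")
            continue
        key = rec.site_key()
        if key is None:
            continue
        acc = sums.setdefault(key, {})
        for sample, value in rec.intensity.items():
            acc[sample] = acc.get(sample, 0.0) + value
    frame = pd.DataFrame.from_dict(sums, orient="index").fillna(0.0)
    frame = frame.sort_index()
    return SiteQuantTable(frame=frame, rejected=rejected)


@dataclass
class AcetylChangeResults:
    """Per-site-combination change statistics (mutant - reference)."""

    table: pd.DataFrame  # difference, se, t, p, d, q, significant
    contrast: tuple[str, str]
    params: TestParams

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        lines = [
            f"Acetylation change, {self.contrast[0]} vs {self.contrast[1]} "
            f"(q <= {self.params.fdr_level})"
        ]
        for key, row in self.table.sort_values("q").iterrows():
            mark = "*" if row["significant"] else " "
            lines.append(
                f"  {mark} {key:<22} log2 change {row['difference']:+6.2f}  "
                f"q={row['q']:.4f}"
            )
        return "\n".join(lines)


def relative_acetylation_change(
    sites: SiteQuantTable,
    design: SampleDesign,
    params: TestParams | None = None,
    impute_params: ImputeParams | None = None,
    normalize: str = "median",
    seed: int = 0,
) -> AcetylChangeResults:
    """Mutant-vs-reference change statistics on the site table.

    ``normalize`` is ``"median"`` (per-sample median centring of log2
    intensities, the default), ``"total"`` (divide by per-sample total
    signal before log2) or ``"none"``.
    """
    if params is None:
        params = TestParams(min_valid=2)
    if impute_params is None:
        impute_params = ImputeParams(seed=seed)
    frame = sites.frame.copy()
    if normalize == "total":
        totals = frame.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total signal")
        frame = frame / totals
    values = frame.where(frame > 0).apply(np.log2)
    m = LogIntensityMatrix(values=values, design=design)
    if normalize == "median":
        m = median_normalize(m)
    elif normalize not in ("none", "total"):
        raise ValueError("normalize must be 'median', 'total' or 'none'")
    m = filter_min_valid(m, params.min_valid)
    if m.values.isna().any().any():
        m = impute_gaussian_downshift(m, impute_params)
    table = permutation_fdr(m, params=params, seed=seed)
    return AcetylChangeResults(
        table=table,
        contrast=(design.treatment, design.control),
        params=params,
    )
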