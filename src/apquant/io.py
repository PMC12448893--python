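"""Readers and writers for the pipeline's file formats.

Protein-group tables follow the MaxQuant ``proteinGroups.txt`` dialect:
tab-separated, one row per protein group, per-sample ``Intensity <sample>``
and ``LFQ intensity <sample>`` columns, and quality-flag columns
(``Reverse``, ``Potential contaminant``, ``Only identified by site``) where
``+`` marks a flagged row.  Zero intensity encodes a missing measurement.

Complex catalogs (which proteins belong to which HDAC-corepressor complex,
and which of them bind the bait directly) are YAML; FASTA goes through
Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO

FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")
_FLAG_ATTRS = ("reverse", "potential_contaminant", "only_identified_by_site")


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


@dataclass
class ProteinGroupsTable:
    """In-memory protein-group table.

    ``frame`` holds one row per protein group with columns:
    ``protein_ids`` (semicolon-joined accessions), ``gene_names``,
    the three boolean flags, ``intensity_<sample>`` and
    ``lfq_intensity_<sample>``.  The index is the primary protein ID
    (first accession of the list, the MaxQuant "majority" convention).
    """

    frame: pd.DataFrame
    samples: list[str]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.frame.index)

    def intensities(self, which: str = "intensity") -> pd.DataFrame:
        """Per-sample intensity matrix (columns named by sample)."""
        prefix = {"intensity": "intensity_", "lfq": "lfq_intensity_"}.get(which)
        if prefix is None:
            raise ValueError("which must be 'intensity' or 'lfq'")
        sub = self.frame[[prefix + s for s in self.samples]].copy()
        sub.columns = self.samples
        return sub


@dataclass
class SampleDesign:
    """Sample-to-group assignment plus the contrast orientation."""

    groups: dict[str, str]
    treatment: str
    control: str

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def validate_against(self, samples: Iterable[str]) -> None:
        missing = [s for s in samples if s not in self.groups]
        if missing:
            raise FormatError(f"samples missing from design: {missing}")


@dataclass
class ComplexDefinition:
    name: str
    members: list[str]
    direct_binders: list[str]
    stoichiometry: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.direct_binders:
            raise ValueError(f"complex {self.name!r} has no direct binders")
        extra = set(self.direct_binders) - set(self.members)
        if extra:
            raise ValueError(
                f"complex {self.name!r}: direct binders not in members: {sorted(extra)}"
            )


@dataclass
class ComplexCatalog:
    """Curated complex membership. A protein may appear in several complexes
    (shared subunits such as RBBP4 sit in both SIN3A and NuRD)."""

    complexes: list[ComplexDefinition]

    def __iter__(self):
        return iter(self.complexes)

    def __len__(self) -> int:
        return len(self.complexes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.complexes]

    def members(self) -> set[str]:
        out: set[str] = set()
        for c in self.complexes:
            out.update(c.members)
        return out


def _sample_names(columns: Iterable[str], prefix: str) -> list[str]:
    names = []
    for col in columns:
        if col.lower().startswith(prefix.lower()) and len(col) > len(prefix):
            names.append(col[len(prefix):])
    return names


def read_protein_groups(path: str | Path) -> ProteinGroupsTable:
    """Parse a MaxQuant-dialect proteinGroups TSV."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        raise FormatError("duplicate column names in header")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                      comment="#")
    if "Protein IDs" not in raw.columns:
        raise FormatError("missing 'Protein IDs' column")
    lfq_samples = _sample_names(raw.columns, "LFQ intensity ")
    int_samples = _sample_names(raw.columns, "Intensity ")
    # "LFQ intensity X" also matches no other prefix; "Intensity X" must not
    # pick up the LFQ columns (it cannot: prefixes differ at position 0).
    samples = int_samples or lfq_samples
    if not samples:
        raise FormatError("no per-sample intensity columns found")
    if len(set(samples)) != len(samples):
        raise FormatError("duplicate sample names in intensity columns")
    if int_samples and lfq_samples and set(int_samples) != set(lfq_samples):
        raise FormatError("Intensity and LFQ intensity sample sets differ")

    frame = pd.DataFrame()
    frame["protein_ids"] = raw["Protein IDs"]
    frame["gene_names"] = raw.get("Gene names", "")
    for col, attr in zip(FLAG_COLUMNS, _FLAG_ATTRS):
        if col in raw.columns:
            frame[attr] = raw[col].str.strip() == "+"
        else:
            frame[attr] = False
    for s in samples:
        src = f"Intensity {s}" if int_samples else f"LFQ intensity {s}"
        frame[f"intensity_{s}"] = pd.to_numeric(raw[src])
        lfq_src = f"LFQ intensity {s}"
        frame[f"lfq_intensity_{s}"] = (
            pd.to_numeric(raw[lfq_src]) if lfq_src in raw.columns
            else frame[f"intensity_{s}"]
        )
        if (frame[f"intensity_{s}"] < 0).any() or (frame[f"lfq_intensity_{s}"] < 0).any():
            raise FormatError(f"negative intensity in sample {s!r}")
    frame.index = pd.Index(
        [ids.split(";")[0] for ids in frame["protein_ids"]], name="protein"
    )
    if frame.index.has_duplicates:
        raise FormatError("duplicate primary protein IDs")
    return ProteinGroupsTable(frame=frame, samples=samples)


def write_protein_groups(table: ProteinGroupsTable, path: str | Path) -> None:
    """Write back in the MaxQuant dialect (inverse of read_protein_groups)."""
    out = pd.DataFrame()
    out["Protein IDs"] = table.frame["protein_ids"].values
    out["Gene names"] = table.frame["gene_names"].values
    for col, attr in zip(FLAG_COLUMNS, _FLAG_ATTRS):
        out[col] = ["+" if v else "" for v in table.frame[attr]]
    for s in table.samples:
        out[f"Intensity {s}"] = table.frame[f"intensity_{s}"].values
    for s in table.samples:
        out[f"LFQ intensity {s}"] = table.frame[f"lfq_intensity_{s}"].values
    out.to_csv(path, sep="\t", index=False)


def filter_flagged(table: ProteinGroupsTable) -> tuple[ProteinGroupsTable, int]:
    """Drop reverse hits, potential contaminants and only-identified-by-site
    rows. Returns the filtered table and the number of rows removed (a row
    with several flags counts once)."""
    flagged = (
        table.frame["reverse"]
        | table.frame["potential_contaminant"]
        | table.frame["only_identified_by_site"]
    )
    kept = table.frame.loc[~flagged].copy()
    return ProteinGroupsTable(frame=kept, samples=list(table.samples)), int(flagged.sum())


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {ID: upper-cased sequence}; ID is the first header token."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {record.id!r}")
        if record.id in out:
            raise FormatError(f"duplicate FASTA ID {record.id!r}")
        out[record.id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_CATALOG_KEYS = {"members", "direct_binders", "stoichiometry"}


def read_complex_catalog(path: str | Path) -> ComplexCatalog:
    """Load a YAML complex catalog.

    Layout::

        NuRD:
          members: [MTA1, MTA2, MTA3, MBD3, CHD4, RBBP4]
          direct_binders: [MTA1, MTA2, MTA3]
          stoichiometry: {RBBP4: 2}      # optional, defaults to 1
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or not data:
        raise FormatError("catalog must be a non-empty mapping")
    complexes = []
    for name, spec in data.items():
        if not isinstance(spec, dict):
            raise FormatError(f"complex {name!r}: expected a mapping")
        unknown = set(spec) - _CATALOG_KEYS
        if unknown:
            raise FormatError(f"complex {name!r}: unknown keys {sorted(unknown)}")
        try:
            cdef = ComplexDefinition(
                name=str(name),
                members=[str(m) for m in spec.get("members", [])],
                direct_binders=[str(d) for d in spec.get("direct_binders", [])],
                stoichiometry={
                    str(k): float(v)
                    for k, v in (spec.get("stoichiometry") or {}).items()
                },
            )
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
        complexes.append(cdef)
    return ComplexCatalog(complexes=complexes)


def write_complex_catalog(catalog: ComplexCatalog, path: str | Path) -> None:
    data = {}
    for c in catalog:
        entry: dict = {"members": c.members, "direct_binders": c.direct_binders}
        if c.stoichiometry:
            entry["stoichiometry"] = c.stoichiometry
        data[c.name] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_design(path: str | Path, treatment: str | None = None,
                control: str | None = None) -> SampleDesign:
    """Design TSV with columns ``sample`` and ``group``.

    Contrast orientation defaults to first-seen group = treatment,
    second = control.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(frame.columns):
        raise FormatError("design file needs 'sample' and 'group' columns")
    if frame["sample"].duplicated().any():
        raise FormatError("duplicate sample in design")
    groups = dict(zip(frame["sample"], frame["group"]))
    order = list(dict.fromkeys(frame["group"]))
    if treatment is None:
        treatment = order[0]
    if control is None:
        control = next((g for g in order if g != treatment), treatment)
    for g in (treatment, control):
        if g not in order:
            raise FormatError(f"group {g!r} not present in design")
    return SampleDesign(groups=groups, treatment=treatment, control=control)


def write_design(design: SampleDesign, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(design.groups), "group": list(design.groups.values())}
    ).to_csv(path, sep="\t", index=False)


def write_results(frame: pd.DataFrame, path: str | Path,
                  parameters: Mapping[str, object] | None = None) -> None:
    """Results TSV with a header comment carrying version and parameters."""
    from . import __version__

    with open(path, "w") as fh:
        params = " ".join(f"{k}={v}" for k, v in (parameters or {}).items())
        fh.write(f"# apquant {__version__} {params}".rstrip() + "\n")
        frame.to_csv(fh, sep="\t")
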