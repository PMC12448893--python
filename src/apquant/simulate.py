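"""Synthetic bait-pulldown and histone-peptide data generator.

The generator emulates a Flag-tagged bait co-immunoprecipitation read out
by label-free LC-MS/MS at the protein-group level:

* a ground-truth scenario partitions the bait among competing multiprotein
  complexes (each with one or more direct-binder subunits that contact the
  bait 1:1, plus non-direct members at configurable stoichiometry);
* expected linear intensity of a protein is copy number x observable
  tryptic peptide count x a single global response factor, so iBAQ
  (intensity / peptide count) recovers copy numbers by construction;
* replicate measurements carry multiplicative log-normal noise and an
  intensity-dependent (missing-not-at-random) dropout: the probability a
  measurement is lost follows a decreasing logistic in log2 intensity;
* control samples (no tagged bait) contain only background contaminants,
  which appear in both groups at equal expected intensity.

All randomness derives from one master seed through named substreams, so
adding a simulation stage never perturbs another stage's draws.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import AMINO_ACIDS, DigestParams, count_observable_peptides
from .io import ProteinGroupsTable, SampleDesign


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named RNG stream derived from a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class GroundTruth:
    """The scenario a simulation realises and the recovery target.

    ``copy_number`` is in arbitrary linear units (molecules per pulldown up
    to a constant).  Direct-binder copies within complex ``c`` sum to
    ``true_proportions[c] * bait_amount * occupancy``; occupancy < 1 models
    free (uncomplexed) bait.
    """

    complexes: list[tuple[str, list[str], list[str]]]
    copy_number: dict[str, float]
    bait_id: str
    bait_amount: float
    occupancy: float
    true_proportions: dict[str, float]
    background_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, members, direct in self.complexes:
            if not direct:
                raise ValueError(f"complex {name!r} has no direct binders")
            if not set(direct) <= set(members):
                raise ValueError(f"complex {name!r}: direct binders not subset of members")
        total = sum(self.true_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, expected 1")
        bound = sum(
            self.copy_number[d] for _, _, direct in self.complexes for d in direct
        )
        if bound > self.bait_amount * (1 + 1e-9):
            raise ValueError("direct-binder copies exceed bait amount (1:1 binding)")

    @property
    def interactor_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, members, _ in self.complexes:
            for m in members:
                seen.setdefault(m)
        return list(seen)

    def catalog(self):
        """ComplexCatalog describing this scenario's complexes."""
        from .io import ComplexCatalog, ComplexDefinition

        return ComplexCatalog(
            [ComplexDefinition(n, list(m), list(d)) for n, m, d in self.complexes]
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["complexes"] = [tuple(c) for c in data["complexes"]]
        return cls(**data)


@dataclass(frozen=True)
class SequenceParams:
    """Random-protein parameters: length range and residue composition.

    Default K+R frequency of 0.11 matches the tryptic-site density of a
    typical proteome; proline (which Trypsin/P cleaves through anyway)
    is set near its natural abundance.
    """

    min_length: int = 200
    max_length: int = 1500
    kr_frequency: float = 0.11
    p_frequency: float = 0.05

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.min_length > self.max_length:
            raise ValueError("empty or invalid sequence length range")
        if self.kr_frequency + self.p_frequency > 1:
            raise ValueError("residue frequencies exceed 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Measurement-model settings.

    ``noise_sd_log2`` is the replicate-to-replicate standard deviation of
    multiplicative measurement noise, in log2 units (0.2 is typical for
    label-free AP-MS).  Dropout probability for a measurement with log2
    intensity x is ``sigmoid(-dropout_steepness * (x - dropout_midpoint_log2))``,
    i.e. faint signals vanish preferentially (MNAR).
    """

    n_replicates_per_group: int = 4
    n_control_replicates: int | None = None  # defaults to symmetric
    noise_sd_log2: float = 0.2
    dropout: bool = True
    dropout_midpoint_log2: float = 20.0
    dropout_steepness: float = 1.0
    response_factor: float = 1e5
    seed: int = 0
    sequence_params: SequenceParams = field(default_factory=SequenceParams)

    def __post_init__(self) -> None:
        if self.n_replicates_per_group < 1:
            raise ValueError("need at least one replicate per group")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if self.dropout_steepness <= 0:
            raise ValueError("dropout_steepness must be > 0")

    @property
    def n_controls(self) -> int:
        return self.n_control_replicates or self.n_replicates_per_group


@dataclass
class SyntheticDataset:
    protein_groups: ProteinGroupsTable
    fasta: dict[str, str]
    truth: GroundTruth
    design: SampleDesign


def generate_ground_truth(
    n_complexes: int = 6,
    members_per_complex: tuple[int, int] = (4, 8),
    n_background: int = 100,
    proportions: Sequence[float] = (0.49, 0.28, 0.15, 0.04, 0.03, 0.01),
    bait_amount: float = 100.0,
    occupancy: float = 0.91,
    direct_binders_per_complex: tuple[int, int] = (1, 3),
    stoich_multipliers: Mapping[str, float] | None = None,
    background_copy_range_log10: tuple[float, float] = (-1.0, 1.5),
    seed: int = 0,
) -> GroundTruth:
    """Draw a complex-partition scenario.

    Complex ``c`` receives fraction ``proportions[c]`` of the bound bait;
    its direct binders split that amount (1:1 binding, so their copies sum
    to ``proportions[c] * bait_amount * occupancy``).  Non-direct members
    get the complex amount scaled by a per-subunit stoichiometry multiplier
    (default 1; pass e.g. ``{"C0_M3": 2.0}`` for a doubly-present subunit).
    Background contaminants draw copies log-uniformly, identical in bait
    and control pulldowns.
    """
    proportions = list(proportions)
    if len(proportions) != n_complexes:
        raise ValueError("n_complexes must equal len(proportions)")
    if any(p < 0 for p in proportions):
        raise ValueError("proportions must be nonnegative")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {sum(proportions)}, expected 1")
    if not 0 < occupancy <= 1:
        raise ValueError("occupancy must be in (0, 1]")
    rng = substream(seed, "ground_truth")
    stoich = dict(stoich_multipliers or {})

    complexes = []
    copy_number: dict[str, float] = {}
    true_proportions: dict[str, float] = {}
    for c, frac in enumerate(proportions):
        name = f"CPX{c}"
        n_members = int(rng.integers(members_per_complex[0], members_per_complex[1] + 1))
        n_direct = int(
            rng.integers(
                direct_binders_per_complex[0],
                min(direct_binders_per_complex[1], n_members) + 1,
            )
        )
        members = [f"{name}_M{i}" for i in range(n_members)]
        direct = members[:n_direct]
        amount = frac * bait_amount * occupancy
        # Direct binders split the complex's bait share (Dirichlet weights).
        weights = rng.dirichlet(np.ones(n_direct)) if n_direct > 1 else np.ones(1)
        for d, w in zip(direct, weights):
            copy_number[d] = float(amount * w)
        for m in members[n_direct:]:
            copy_number[m] = float(amount * stoich.get(m, 1.0))
        complexes.append((name, members, direct))
        true_proportions[name] = float(frac)

    bait_id = "BAIT"
    copy_number[bait_id] = float(bait_amount)
    background_ids = [f"BG{i}" for i in range(n_background)]
    lo, hi = background_copy_range_log10
    for b in background_ids:
        copy_number[b] = float(10 ** rng.uniform(lo, hi))
    return GroundTruth(
        complexes=complexes,
        copy_number=copy_number,
        bait_id=bait_id,
        bait_amount=float(bait_amount),
        occupancy=float(occupancy),
        true_proportions=true_proportions,
        background_ids=background_ids,
    )


def generate_sequences(
    truth: GroundTruth,
    params: SequenceParams | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Random amino-acid sequences for every protein in the scenario."""
    if params is None:
        params = SequenceParams()
    rng = substream(seed, "sequences")
    other = [a for a in AMINO_ACIDS if a not in "KRP"]
    p_kr = params.kr_frequency / 2.0
    probs = np.array(
        [p_kr, p_kr, params.p_frequency]
        + [(1 - params.kr_frequency - params.p_frequency) / len(other)] * len(other)
    )
    alphabet = np.array(list("KRP") + other)
    out: dict[str, str] = {}
    ids = [truth.bait_id] + truth.interactor_ids + truth.background_ids
    for pid in ids:
        n = int(rng.integers(params.min_length, params.max_length + 1))
        out[pid] = "".join(rng.choice(alphabet, size=n, p=probs))
    return out


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_pulldown(
    truth: GroundTruth,
    fasta: Mapping[str, str],
    config: SimulationConfig,
) -> SyntheticDataset:
    """Simulate a bait-vs-control pulldown protein-group table.

    Bait-group samples contain the bait, all complex members and the
    background; control samples contain background only.  Missing
    measurements are written as zero intensity (MaxQuant convention);
    LFQ and raw intensity columns are identical in simulation.
    """
    all_ids = [truth.bait_id] + truth.interactor_ids + truth.background_ids
    missing_seq = [p for p in all_ids if p not in fasta]
    if missing_seq:
        raise ValueError(f"proteins without sequences: {missing_seq}")

    digest_params = DigestParams()
    counts = {p: count_observable_peptides(fasta[p], digest_params) for p in all_ids}
    zero_obs = [p for p, c in counts.items() if c == 0]
    if zero_obs:
        import warnings

        warnings.warn(
            f"{len(zero_obs)} protein(s) with zero observable peptides "
            "simulate at intensity 0",
            stacklevel=2,
        )

    bait_samples = [f"bait_{i + 1}" for i in range(config.n_replicates_per_group)]
    ctrl_samples = [f"control_{i + 1}" for i in range(config.n_controls)]
    samples = bait_samples + ctrl_samples
    bait_set = set(bait_samples)
    background = set(truth.background_ids)

    noise_rng = substream(config.seed, "noise")
    dropout_rng = substream(config.seed, "dropout")

    expected = {
        p: truth.copy_number[p] * counts[p] * config.response_factor for p in all_ids
    }
    data: dict[str, list[float]] = {s: [] for s in samples}
    for p in all_ids:
        for s in samples:
            present_in_sample = (s in bait_set) or (p in background)
            if not present_in_sample or expected[p] <= 0:
                value = 0.0
            else:
                value = expected[p]
                if config.noise_sd_log2 > 0:
                    value *= 2.0 ** noise_rng.normal(0.0, config.noise_sd_log2)
                if config.dropout:
                    p_miss = float(
                        _logistic(
                            -config.dropout_steepness
                            * (np.log2(value) - config.dropout_midpoint_log2)
                        )
                    )
                    if dropout_rng.random() < p_miss:
                        value = 0.0
            data[s].append(value)

    frame = pd.DataFrame({"protein_ids": all_ids, "gene_names": all_ids})
    frame["reverse"] = False
    frame["potential_contaminant"] = False
    frame["only_identified_by_site"] = False
    for s in samples:
        frame[f"intensity_{s}"] = data[s]
        frame[f"lfq_intensity_{s}"] = data[s]
    frame.index = pd.Index(all_ids, name="protein")

    design = SampleDesign(
        groups={**{s: "bait" for s in bait_samples}, **{s: "control" for s in ctrl_samples}},
        treatment="bait",
        control="control",
    )
    return SyntheticDataset(
        protein_groups=ProteinGroupsTable(frame=frame, samples=samples),
        fasta=dict(fasta),
        truth=truth,
        design=design,
    )


def planted_interactor_truth(
    n_interactors: int = 148,
    n_complexes: int = 6,
    n_background: int = 1000,
    bait_amount: float = 1000.0,
    occupancy: float = 0.91,
    seed: int = 0,
) -> GroundTruth:
    """Screen scenario: exactly ``n_interactors`` true complex members.

    Members are spread near-equally over ``n_complexes`` complexes with
    equal proportions, so with a large ``bait_amount`` every interactor
    sits far above the detection floor (a strong-effect enrichment screen,
    as opposed to the unequal-partition stoichiometry scenarios of
    :func:`generate_ground_truth`).
    """
    rng = substream(seed, "planted_truth")
    base, extra = divmod(n_interactors, n_complexes)
    sizes = [base + (1 if c < extra else 0) for c in range(n_complexes)]
    proportions = np.full(n_complexes, 1.0 / n_complexes)
    proportions[-1] = 1.0 - proportions[:-1].sum()

    complexes = []
    copy_number: dict[str, float] = {}
    true_proportions: dict[str, float] = {}
    for c, (size, frac) in enumerate(zip(sizes, proportions)):
        name = f"CPX{c}"
        members = [f"{name}_M{i}" for i in range(size)]
        direct = members[:1]
        amount = frac * bait_amount * occupancy
        copy_number[direct[0]] = float(amount)
        for m in members[1:]:
            copy_number[m] = float(amount)
        complexes.append((name, members, direct))
        true_proportions[name] = float(frac)
    copy_number["BAIT"] = float(bait_amount)
    background_ids = [f"BG{i}" for i in range(n_background)]
    for b in background_ids:
        copy_number[b] = float(10 ** rng.uniform(-1.0, 1.5))
    return GroundTruth(
        complexes=complexes,
        copy_number=copy_number,
        bait_id="BAIT",
        bait_amount=float(bait_amount),
        occupancy=float(occupancy),
        true_proportions=true_proportions,
        background_ids=background_ids,
    )


# --- histone peptide simulation ------------------------------------------

#: Histone tail peptides produced by tryptic digestion of propionylated
#: histones (Arg-C-like specificity), with the acetylatable lysines each
#: carries.  Positions use mature-protein numbering (initiator Met removed).
#: Sequences are synthetic stand-ins with the canonical site spacing.
HISTONE_PEPTIDES: dict[str, dict] = {
    "H3_9_17": {"histone": "H3", "start": 9, "sequence": "KSTGGKAPR", "k_sites": [9, 14]},
    "H3_18_26": {"histone": "H3", "start": 18, "sequence": "KQLATKAAR", "k_sites": [18, 23]},
    "H4_4_17": {"histone": "H4", "start": 4, "sequence": "GKGGKGLGKGGAKR", "k_sites": [5, 8, 12, 16]},
    "H2B_12_24": {"histone": "H2B", "start": 12, "sequence": "KGSKKAVTKAQKK", "k_sites": [12, 15, 20]},
}


def known_site_combinations() -> list[str]:
    """All site-combination keys the simulator can emit."""
    keys = []
    for info in HISTONE_PEPTIDES.values():
        sites = info["k_sites"]
        for mask in range(1, 2 ** len(sites)):
            combo = [s for i, s in enumerate(sites) if mask >> i & 1]
            keys.append(f"{info['histone']} " + "+".join(f"K{s}ac" for s in combo))
    return keys


def simulate_histone_peptides(
    site_occupancies_by_group: Mapping[str, Mapping[str, float]],
    n_replicates: int = 4,
    noise_sd_log2: float = 0.0,
    base_intensity: float = 1e8,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a modified-peptide table for histone acetylation analysis.

    ``site_occupancies_by_group`` maps group label -> {site-combination key
    (e.g. ``"H3 K18ac"`` or ``"H3 K18ac+K23ac"``) -> fractional occupancy}.
    Each occupied combination yields an acetylated peptide record whose
    intensity is ``base_intensity * occupancy``; the remaining fraction is
    emitted as the fully-propionylated (unmodified) form.  Occupancy
    differences between groups therefore propagate 1:1 to intensity ratios.

    Returns a table with columns: protein, sequence, start, modifications
    (semicolon-joined ``pos:type`` in peptide offsets), and one
    ``Intensity <group>_<r>`` column per replicate.
    """
    valid = set(known_site_combinations())
    for group, occ in site_occupancies_by_group.items():
        for key, frac in occ.items():
            if key not in valid:
                raise ValueError(f"unknown site combination {key!r}")
            if not 0 <= frac <= 1:
                raise ValueError(f"occupancy for {key!r} outside [0, 1]")

    rng = substream(seed, "histone_noise")
    groups = list(site_occupancies_by_group)
    sample_names = [f"{g}_{r + 1}" for g in groups for r in range(n_replicates)]

    def peptide_for(key: str) -> tuple[dict, list[int]]:
        histone, combo = key.split(" ", 1)
        positions = [int(tok[1:-2]) for tok in combo.split("+")]
        for info in HISTONE_PEPTIDES.values():
            if info["histone"] == histone and set(positions) <= set(info["k_sites"]):
                return info, positions
        raise ValueError(f"unknown site combination {key!r}")

    rows: dict[tuple, dict] = {}
    all_keys = sorted({k for occ in site_occupancies_by_group.values() for k in occ})
    for key in all_keys:
        info, positions = peptide_for(key)
        offsets = [p - info["start"] + 1 for p in positions]
        ac_mods = ";".join(f"{o}:acetyl" for o in offsets)
        prop_offsets = [s - info["start"] + 1 for s in info["k_sites"] if s not in positions]
        mods = ";".join(
            [ac_mods] + [f"{o}:propionyl" for o in prop_offsets]
        ).strip(";")
        row_key = (info["histone"], info["sequence"], info["start"], mods)
        row = rows.setdefault(
            row_key,
            {
                "protein": info["histone"],
                "sequence": info["sequence"],
                "start": info["start"],
                "modifications": mods,
                **{f"Intensity {s}": 0.0 for s in sample_names},
            },
        )
        for g in groups:
            frac = site_occupancies_by_group[g].get(key, 0.0)
            for r in range(n_replicates):
                value = base_intensity * frac
                if value > 0 and noise_sd_log2 > 0:
                    value *= 2.0 ** rng.normal(0.0, noise_sd_log2)
                row[f"Intensity {g}_{r + 1}"] += value

    # fully-propionylated (unmodified) counterpart per peptide
    for pep_id, info in HISTONE_PEPTIDES.items():
        combos_here = [
            (g, key)
            for g in groups
            for key in site_occupancies_by_group[g]
            if peptide_for(key)[0] is info
        ]
        if not combos_here:
            continue
        mods = ";".join(
            f"{s - info['start'] + 1}:propionyl" for s in info["k_sites"]
        )
        row_key = (info["histone"], info["sequence"], info["start"], mods)
        row = rows.setdefault(
            row_key,
            {
                "protein": info["histone"],
                "sequence": info["sequence"],
                "start": info["start"],
                "modifications": mods,
                **{f"Intensity {s}": 0.0 for s in sample_names},
            },
        )
        for g in groups:
            occupied = sum(
                site_occupancies_by_group[g].get(key, 0.0)
                for key in site_occupancies_by_group[g]
                if peptide_for(key)[0] is info
            )
            frac = max(0.0, 1.0 - occupied)
            for r in range(n_replicates):
                value = base_intensity * frac
                if value > 0 and noise_sd_log2 > 0:
                    value *= 2.0 ** rng.normal(0.0, noise_sd_log2)
                row[f"Intensity {g}_{r + 1}"] += value

    return pd.DataFrame(list(rows.values()))
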