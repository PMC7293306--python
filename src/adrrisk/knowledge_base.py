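"""Drug -> ADR frequency knowledge base.

Holds the side-effect frequency table (one row per drug / MedDRA Preferred
Term pair, frequency as a proportion), the PT -> System Organ Class map, and
an optional term-harmonization map (synonym PT -> canonical PT).  The main
query is :meth:`KnowledgeBase.candidate_adr_profile`: for a drug combination,
collect every PT listed for at least one of the drugs together with the
per-drug frequencies that feed the frequency score.

File dialects are deliberately minimal UTF-8 TSVs (headers ``drug/pt/frequency``,
``pt/soc``, ``synonym/canonical``); they are this package's own formats, not
native SIDER or MedDRA flat files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import FormatError, UnknownDrugWarning, ValidationError

__all__ = [
    "ADRTerm",
    "DrugADRFrequency",
    "HarmonizationMap",
    "CandidateADRProfile",
    "KnowledgeBase",
    "canonical_drug",
    "canonical_pt",
    "load_drug_adr_table",
    "load_soc_map",
    "load_harmonization_map",
    "apply_harmonization",
    "write_drug_adr_table",
    "write_soc_map",
]

MERGE_POLICIES = ("max", "mean")


def canonical_drug(name: str) -> str:
    """Canonical drug spelling: whitespace-collapsed, lower-cased."""
    return " ".join(name.split()).lower()


def canonical_pt(name: str) -> str:
    """Canonical Preferred Term spelling: whitespace-collapsed, sentence-cased.

    Source capitalization (SIDER vs FAERS) is inconsistent, so matching is
    case-insensitive and terms are stored with the MedDRA-style leading capital.
    """
    s = " ".join(name.split())
    return s[:1].upper() + s[1:].lower()


@dataclass(frozen=True)
class ADRTerm:
    """A Preferred Term together with its System Organ Class."""

    pt_name: str
    soc_name: str

    def __post_init__(self) -> None:
        if not self.pt_name:
            raise ValidationError("ADR preferred term must be non-empty")


@dataclass(frozen=True)
class DrugADRFrequency:
    """One knowledge-base row: the average frequency of a PT for a drug."""

    drug_name: str
    pt_name: str
    frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValidationError(
                f"frequency for ({self.drug_name}, {self.pt_name}) is "
                f"{self.frequency}, outside [0, 1]"
            )


@dataclass(frozen=True)
class CandidateADRProfile:
    """A candidate ADR for a drug combination with each contributing drug's frequency."""

    pt_name: str
    soc_name: str
    contributing_frequencies: tuple[tuple[str, float], ...]

    @property
    def frequencies(self) -> list[float]:
        return [f for _, f in self.contributing_frequencies]


class HarmonizationMap:
    """Synonym PT -> canonical PT renaming map.

    The map must be idempotent: a canonical term may never itself appear as a
    synonym, so one application is a fixed point and cycles are impossible.
    """

    def __init__(self, entries: Mapping[str, str]):
        canon = {canonical_pt(k): canonical_pt(v) for k, v in entries.items()}
        bad = sorted(set(canon.values()) & set(canon.keys()))
        if bad:
            raise ValidationError(
                f"harmonization map is not idempotent: canonical term(s) "
                f"{bad} also appear as synonyms"
            )
        self.entries: dict[str, str] = canon

    def resolve(self, pt_name: str) -> str:
        pt = canonical_pt(pt_name)
        return self.entries.get(pt, pt)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, HarmonizationMap) and self.entries == other.entries


def _merge_frequencies(values: Sequence[float], policy: str) -> float:
    if policy == "max":
        return max(values)
    if policy == "mean":
        return sum(values) / len(values)
    raise ValidationError(f"unknown merge policy {policy!r}; expected one of {MERGE_POLICIES}")


def _parse_frequency(raw: str, row_number: int) -> float:
    """Accept a proportion ('0.12') or a percentage with trailing % ('12%')."""
    text = str(raw).strip()
    scale = 1.0
    if text.endswith("%"):
        text = text[:-1].strip()
        scale = 0.01
    try:
        value = float(text) * scale
    except ValueError:
        raise ValidationError(
            f"row {row_number}: frequency {raw!r} is not a number"
        ) from None
    if not 0.0 <= value <= 1.0:
        raise ValidationError(
            f"row {row_number}: frequency {value} outside [0, 1]"
        )
    return value


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in required:
        if column not in frame.columns:
            raise FormatError(f"{path}: missing required column {column!r}")
    return frame


def load_drug_adr_table(
    path: str | Path, merge_policy: str = "max"
) -> list[DrugADRFrequency]:
    """Load the drug -> ADR frequency TSV (header ``drug\\tpt\\tfrequency``).

    Duplicate (drug, PT) rows are merged under ``merge_policy`` ("max" keeps
    the worst-case frequency, "mean" averages).  Row numbers in error messages
    are 1-based over data rows.
    """
    frame = _read_tsv(path, ("drug", "pt", "frequency"))
    grouped: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[str, str]] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        key = (canonical_drug(row.drug), canonical_pt(row.pt))
        if not key[0] or not key[1]:
            raise ValidationError(f"row {i}: empty drug or PT name")
        freq = _parse_frequency(row.frequency, i)
        if key not in grouped:
            order.append(key)
        grouped.setdefault(key, []).append(freq)
    return [
        DrugADRFrequency(drug, pt, _merge_frequencies(grouped[(drug, pt)], merge_policy))
        for drug, pt in order
    ]


def load_soc_map(path: str | Path) -> dict[str, str]:
    """Load the PT -> SOC TSV (header ``pt\\tsoc``); conflicting rows are an error."""
    frame = _read_tsv(path, ("pt", "soc"))
    mapping: dict[str, str] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        pt = canonical_pt(row.pt)
        soc = " ".join(str(row.soc).split())
        if not pt or not soc:
            raise ValidationError(f"row {i}: empty PT or SOC name")
        if pt in mapping and mapping[pt] != soc:
            raise ValidationError(
                f"PT {pt!r} mapped to two different SOCs: {mapping[pt]!r} and {soc!r}"
            )
        mapping[pt] = soc
    return mapping


def load_harmonization_map(path: str | Path) -> HarmonizationMap:
    """Load the synonym -> canonical PT TSV (header ``synonym\\tcanonical``)."""
    frame = _read_tsv(path, ("synonym", "canonical"))
    return HarmonizationMap(
        {row.synonym: row.canonical for row in frame.itertuples(index=False)}
    )


def apply_harmonization(
    records: Iterable[DrugADRFrequency],
    hmap: HarmonizationMap,
    merge_policy: str = "max",
) -> list[DrugADRFrequency]:
    """Rename synonym PTs to their canonical terms, merging any collisions.

    Idempotent: because no canonical term is itself a synonym, applying the
    result to the same map again is the identity.
    """
    grouped: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[str, str]] = []
    for record in records:
        key = (record.drug_name, hmap.resolve(record.pt_name))
        if key not in grouped:
            order.append(key)
        grouped.setdefault(key, []).append(record.frequency)
    return [
        DrugADRFrequency(drug, pt, _merge_frequencies(grouped[(drug, pt)], merge_policy))
        for drug, pt in order
    ]


def write_drug_adr_table(records: Iterable[DrugADRFrequency], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.drug_name, r.pt_name, repr(r.frequency)) for r in records],
        columns=["drug", "pt", "frequency"],
    )
    frame.to_csv(path, sep="\t", index=False)


def write_soc_map(soc_map: Mapping[str, str], path: str | Path) -> None:
    frame = pd.DataFrame(sorted(soc_map.items()), columns=["pt", "soc"])
    frame.to_csv(path, sep="\t", index=False)


@dataclass
class KnowledgeBase:
    """Harmonized frequency records plus the PT -> SOC map, indexed for queries."""

    records: list[DrugADRFrequency]
    soc_map: dict[str, str]
    _by_drug: dict[str, dict[str, float]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_drug = {}
        for record in self.records:
            per_drug = self._by_drug.setdefault(record.drug_name, {})
            if record.pt_name in per_drug:
                raise ValidationError(
                    f"duplicate (drug, PT) pair after harmonization: "
                    f"({record.drug_name}, {record.pt_name})"
                )
            per_drug[record.pt_name] = record.frequency
        missing = sorted(
            {r.pt_name for r in self.records} - set(self.soc_map)
        )
        if missing:
            raise ValidationError(
                f"PT(s) without a SOC annotation: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )

    @property
    def drugs(self) -> list[str]:
        return sorted(self._by_drug)

    @property
    def pts(self) -> list[str]:
        return sorted({r.pt_name for r in self.records})

    def soc_of(self, pt_name: str) -> str:
        pt = canonical_pt(pt_name)
        if pt not in self.soc_map:
            raise ValidationError(f"PT {pt!r} has no SOC annotation")
        return self.soc_map[pt]

    def candidate_adr_profile(self, drugs: Iterable[str]) -> list[CandidateADRProfile]:
        """All PTs listed for at least one queried drug, with per-drug frequencies.

        Drugs absent from the knowledge base contribute nothing and raise an
        :class:`UnknownDrugWarning`.  An empty drug set yields an empty profile.
        """
        known: list[str] = []
        unknown: list[str] = []
        for name in sorted({canonical_drug(d) for d in drugs}):
            (known if name in self._by_drug else unknown).append(name)
        if unknown:
            warnings.warn(
                f"drug(s) not in knowledge base, ignored: {', '.join(unknown)}",
                UnknownDrugWarning,
                stacklevel=2,
            )
        per_pt: dict[str, list[tuple[str, float]]] = {}
        for drug in known:
            for pt, freq in self._by_drug[drug].items():
                per_pt.setdefault(pt, []).append((drug, freq))
        return [
            CandidateADRProfile(pt, self.soc_of(pt), tuple(contributions))
            for pt, contributions in sorted(per_pt.items())
        ]

    @classmethod
    def load(
        cls,
        drug_adr_path: str | Path,
        soc_path: str | Path,
        harmonization_path: str | Path | None = None,
        merge_policy: str = "max",
    ) -> "KnowledgeBase":
        records = load_drug_adr_table(drug_adr_path, merge_policy=merge_policy)
        soc_map = load_soc_map(soc_path)
        if harmonization_path is not None:
            hmap = load_harmonization_map(harmonization_path)
            records = apply_harmonization(records, hmap, merge_policy=merge_policy)
            soc_map = {hmap.resolve(pt): soc for pt, soc in soc_map.items()}
        return cls(records, soc_map)
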