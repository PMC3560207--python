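"""Evidence-table readers and identifier reconciliation.

Two experimentally validated interaction tables feed the network:

* a miRNA -> target table (miRTarBase-style): which mRNAs each miRNA
  represses;
* a regulator -> miRNA table (TransmiR-style): which transcription factors
  or upstream signaling proteins control each miRNA's transcription, and in
  which direction.

The two sources use different gene identifier conventions, so all gene
fields are mapped to one gene-symbol namespace and all miRNA names to one
canonical form before the tables are joined.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from collections.abc import Iterable, Sequence
from pathlib import Path
from typing import Union

import pandas as pd

__all__ = [
    "ROLES",
    "DIRECTIONS",
    "TargetInteraction",
    "RegulatorInteraction",
    "IdentifierMap",
    "canonical_mirna",
    "canonicalize_records",
    "read_target_table",
    "read_regulator_table",
    "map_identifiers",
    "tf_signaling_universe",
]

logger = logging.getLogger(__name__)

ROLES = ("TF", "signaling")
DIRECTIONS = ("activation", "repression", "unknown")


@dataclasses.dataclass(frozen=True)
class TargetInteraction:
    """One validated miRNA -> target-mRNA interaction."""

    mirna: str
    target: str
    evidence: str = ""


@dataclasses.dataclass(frozen=True)
class RegulatorInteraction:
    """One validated regulator -> miRNA interaction (TF or signaling protein)."""

    regulator: str
    role: str
    direction: str
    mirna: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown regulator role {self.role!r}; expected one of {ROLES}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}; expected one of {DIRECTIONS}")


class IdentifierMap:
    """Foreign identifier -> gene symbol map (one symbol per foreign id)."""

    def __init__(self, mapping: dict[str, str]):
        self.mapping = dict(mapping)
        self.symbols = set(self.mapping.values())

    def __len__(self) -> int:
        return len(self.mapping)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "IdentifierMap":
        mapping: dict[str, str] = {}
        for foreign, symbol in pairs:
            if foreign in mapping and mapping[foreign] != symbol:
                raise ValueError(f"foreign id {foreign!r} maps to both {mapping[foreign]!r} and {symbol!r}")
            mapping[foreign] = symbol
        return cls(mapping)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "IdentifierMap":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        _require_columns(df, ("foreign_id", "gene_symbol"), path)
        return cls.from_pairs(zip(df["foreign_id"], df["gene_symbol"]))

    def to_tsv(self, path: Union[str, Path]) -> None:
        rows = sorted(self.mapping.items())
        pd.DataFrame(rows, columns=["foreign_id", "gene_symbol"]).to_csv(path, sep="\t", index=False)


_MICRORNA_RE = re.compile(r"^(hsa-)?(microrna|mirna|mir)[-_ ]?", re.IGNORECASE)


def canonical_mirna(name: str) -> str:
    """Canonical lowercase miRNA name: ``"miR-221"`` -> ``"hsa-mir-221"``.

    Lowercases, unifies the microRNA/miR/mir prefix to ``mir-``, and adds the
    human ``hsa-`` species prefix if absent. Arm suffixes (``-5p``/``-3p``)
    are preserved. Idempotent.
    """
    if not name or not name.strip():
        raise ValueError("empty miRNA name")
    s = name.strip().lower()
    m = _MICRORNA_RE.match(s)
    if m:
        s = "mir-" + s[m.end():]
    if s.startswith("let-") or s.startswith("mir-"):
        s = "hsa-" + s
    elif not s.startswith("hsa-"):
        s = "hsa-" + s
    return s


def canonicalize_records(records: Sequence) -> list:
    """Return records with their ``mirna`` field canonicalized."""
    return [dataclasses.replace(r, mirna=canonical_mirna(r.mirna)) for r in records]


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_target_table(path: Union[str, Path]) -> list[TargetInteraction]:
    """Read a miRTarBase-style TSV (columns ``mirna``, ``target``,
    optional ``evidence``; order free). Rows with an empty miRNA or target
    are skipped with a logged count; duplicate rows collapse to one record.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("mirna", "target"), path)
    if "evidence" not in df.columns:
        df["evidence"] = ""
    records: list[TargetInteraction] = []
    seen: set[tuple[str, str]] = set()
    skipped = 0
    for row in df.itertuples(index=False):
        mirna, target = row.mirna.strip(), row.target.strip()
        if not mirna or not target:
            skipped += 1
            continue
        key = (mirna, target)
        if key in seen:
            continue
        seen.add(key)
        records.append(TargetInteraction(mirna, target, row.evidence.strip()))
    if skipped:
        logger.info("read_target_table(%s): skipped %d row(s) with empty keys", path, skipped)
    return records


def read_regulator_table(path: Union[str, Path]) -> list[RegulatorInteraction]:
    """Read a TransmiR-style TSV (columns ``regulator``, ``role``,
    ``direction``, ``mirna``). Role vocabulary is enforced; a blank
    direction defaults to ``unknown``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("regulator", "role", "direction", "mirna"), path)
    records: list[RegulatorInteraction] = []
    seen: set[tuple[str, str, str, str]] = set()
    skipped = 0
    for row in df.itertuples(index=False):
        regulator, mirna = row.regulator.strip(), row.mirna.strip()
        if not regulator or not mirna:
            skipped += 1
            continue
        direction = row.direction.strip() or "unknown"
        rec = RegulatorInteraction(regulator, row.role.strip(), direction, mirna)
        key = dataclasses.astuple(rec)
        if key in seen:
            continue
        seen.add(key)
        records.append(rec)
    if skipped:
        logger.info("read_regulator_table(%s): skipped %d row(s) with empty keys", path, skipped)
    return records


def map_identifiers(records: Sequence, idmap: IdentifierMap, field: str) -> tuple[list, list]:
    """Resolve one gene field of each record to the symbol namespace.

    A field value present in the map is replaced by its symbol; a value that
    already is a symbol (member of the map's value set) is left unchanged;
    records that resolve neither way are returned in the second list, never
    silently dropped. ``len(mapped) + len(unmapped) == len(records)``.
    """
    mapped: list = []
    unmapped: list = []
    for rec in records:
        value = getattr(rec, field)
        if value in idmap.mapping:
            mapped.append(dataclasses.replace(rec, **{field: idmap.mapping[value]}))
        elif value in idmap.symbols:
            mapped.append(rec)
        else:
            unmapped.append(rec)
    if unmapped:
        logger.info("map_identifiers: %d record(s) unresolved on field %r", len(unmapped), field)
    return mapped, unmapped


def tf_signaling_universe(
    regulators: Sequence[RegulatorInteraction],
    extra: Iterable[str] = (),
) -> frozenset[str]:
    """The TF/signaling gene universe used to restrict circuit targets:
    every gene acting as a regulator, plus an optional user-supplied
    annotation list."""
    return frozenset(r.regulator for r in regulators) | frozenset(extra)
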