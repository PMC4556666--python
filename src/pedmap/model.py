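"""Core in-memory data model shared by every pipeline stage.

Genotype calls are stored as a dense ``int8`` matrix with the encoding

====  =============================
code  meaning
====  =============================
 0    homozygous for allele1
 1    heterozygous
 2    homozygous for allele2
-1    missing
====  =============================

Coordinates are 1-based inclusive base pairs throughout, matching the
PLINK text-format convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

HOM1, HET, HOM2, MISSING = 0, 1, 2, -1

SEXES = ("male", "female", "unknown")
PHENOTYPES = ("affected", "unaffected", "unknown")
DECLARED_STATUSES = ("none", "obligate_carrier", "declared_carrier", "declared_noncarrier")

#: Cat-like autosome labels with approximate physical lengths in Mb.
#: The X chromosome is deliberately absent: the mapping model is autosomal.
CAT_AUTOSOMES: dict[str, float] = {
    "A1": 239.0, "A2": 169.0, "A3": 142.0,
    "B1": 205.0, "B2": 154.0, "B3": 148.0, "B4": 144.0,
    "C1": 221.0, "C2": 157.0,
    "D1": 116.0, "D2": 89.0, "D3": 95.0, "D4": 96.0,
    "E1": 63.0, "E2": 62.0, "E3": 42.0,
    "F1": 68.0, "F2": 82.0,
}


class PedmapError(ValueError):
    """Base class for validation and parse errors."""


class ParseError(PedmapError):
    """Raised when an on-disk file violates its format contract."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member with phenotype and optional carrier annotation."""

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = "unknown"
    phenotype: str = "unknown"
    declared_status: str = "none"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise PedmapError(f"invalid sex {self.sex!r} for {self.id!r}")
        if self.phenotype not in PHENOTYPES:
            raise PedmapError(f"invalid phenotype {self.phenotype!r} for {self.id!r}")
        if self.declared_status not in DECLARED_STATUSES:
            raise PedmapError(f"invalid declared_status {self.declared_status!r} for {self.id!r}")
        if (self.sire is None) != (self.dam is None):
            raise PedmapError(
                f"individual {self.id!r} has exactly one known parent; both or none required"
            )

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


class Pedigree:
    """A validated set of individuals with parent links.

    Validation rejects cycles, single known parents, and sex-inconsistent
    parent links (a sire must not be a known female, a dam not a known male).
    Parents referenced but not listed are added as unknown-sex founders.
    """

    def __init__(self, individuals: Iterable[Individual]):
        members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in members:
                raise PedmapError(f"duplicate individual id {ind.id!r}")
            members[ind.id] = ind
        # implicit founders for dangling parent references
        for ind in list(members.values()):
            for pid, sex in ((ind.sire, "male"), (ind.dam, "female")):
                if pid is not None and pid not in members:
                    members[pid] = Individual(pid, sex=sex)
        self._members = members
        self._validate()

    def _validate(self) -> None:
        for ind in self._members.values():
            if ind.sire is not None:
                sire = self._members[ind.sire]
                if sire.sex == "female":
                    raise PedmapError(f"sire {sire.id!r} of {ind.id!r} is female")
                dam = self._members[ind.dam]
                if dam.sex == "male":
                    raise PedmapError(f"dam {dam.id!r} of {ind.id!r} is male")
        # cycle check by DFS over parent links
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                raise PedmapError(f"pedigree cycle involving {iid!r}")
            if state.get(iid) == 2:
                return
            state[iid] = 1
            ind = self._members[iid]
            for pid in (ind.sire, ind.dam):
                if pid is not None:
                    visit(pid)
            state[iid] = 2

        for iid in self._members:
            visit(iid)

    def __iter__(self):
        return iter(self._members.values())

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __getitem__(self, iid: str) -> Individual:
        return self._members[iid]

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    def founders(self) -> list[Individual]:
        return [i for i in self if i.is_founder]

    def children_of(self, iid: str) -> list[Individual]:
        return [i for i in self if iid in (i.sire, i.dam)]

    def topological_order(self) -> list[Individual]:
        """Parents before offspring."""
        order: list[Individual] = []
        seen: set[str] = set()

        def visit(iid: str) -> None:
            if iid in seen:
                return
            ind = self._members[iid]
            for pid in (ind.sire, ind.dam):
                if pid is not None:
                    visit(pid)
            seen.add(iid)
            order.append(ind)

        for iid in self._members:
            visit(iid)
        return order

    def with_declared(self, statuses: Mapping[str, str]) -> "Pedigree":
        """Return a copy with declared carrier statuses applied."""
        updated = []
        for ind in self:
            if ind.id in statuses:
                updated.append(replace(ind, declared_status=statuses[ind.id]))
            else:
                updated.append(ind)
        return Pedigree(updated)


class MarkerMap:
    """Ordered biallelic marker map (chromosome, 1-based bp, id, alleles)."""

    COLUMNS = ("chrom", "id", "pos", "a1", "a2")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise PedmapError(f"marker map missing columns {sorted(missing)}")
        df = table.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        df["pos"] = df["pos"].astype(np.int64)
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise PedmapError(f"duplicate marker id {dup!r}")
        if (df["a1"] == df["a2"]).any():
            bad = df.loc[df["a1"] == df["a2"], "id"].iloc[0]
            raise PedmapError(f"marker {bad!r} has identical allele symbols")
        for chrom, sub in df.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise PedmapError(f"positions not strictly increasing on chromosome {chrom}")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MarkerMap) and self.table.equals(other.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.table["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise PedmapError(f"chromosome {chrom!r} not on map")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def nearest_marker(self, chrom: str, pos: int) -> int:
        """Global index of the marker closest to ``pos`` on ``chrom``."""
        sl = self.chrom_slice(chrom)
        positions = self.table["pos"].to_numpy()[sl]
        return sl.start + int(np.argmin(np.abs(positions - pos)))


@dataclass
class GenotypeMatrix:
    """Biallelic calls for a cohort on a shared marker map."""

    individual_ids: list[str]
    marker_map: MarkerMap
    calls: np.ndarray  # int8, shape (n_individuals, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individual_ids), len(self.marker_map)):
            raise PedmapError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.marker_map)} markers"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise PedmapError("duplicate individual ids in genotype matrix")
        valid = np.isin(self.calls, (HOM1, HET, HOM2, MISSING))
        if not valid.all():
            raise PedmapError("invalid genotype codes in call matrix")

    def row(self, iid: str) -> np.ndarray:
        try:
            return self.calls[self.individual_ids.index(iid)]
        except ValueError:
            raise PedmapError(f"individual {iid!r} not in genotype matrix") from None

    def call_rates(self) -> pd.Series:
        """Fraction of non-missing calls per individual."""
        rate = (self.calls != MISSING).mean(axis=1)
        return pd.Series(rate, index=self.individual_ids, name="call_rate")

    def allele_pair(self, iid: str, marker_index: int) -> tuple[str, str]:
        """Resolve a call into its allele symbols ('0','0' when missing)."""
        call = int(self.row(iid)[marker_index])
        rec = self.marker_map.table.iloc[marker_index]
        return {
            HOM1: (rec.a1, rec.a1),
            HET: (rec.a1, rec.a2),
            HOM2: (rec.a2, rec.a2),
            MISSING: ("0", "0"),
        }[call]


GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt", "missing")


@dataclass
class VariantGenotypeTable:
    """Per-individual genotypes at one biallelic variant.

    ``table`` columns: ``individual`` (str), ``genotype`` (one of
    ``hom_ref|het|hom_alt|missing``) and optional ``breed``.
    """

    variant_id: str
    ref: str
    alt: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = self.table.copy()
        if "individual" not in df.columns or "genotype" not in df.columns:
            raise PedmapError("variant table requires 'individual' and 'genotype' columns")
        if "breed" not in df.columns:
            df["breed"] = ""
        bad = ~df["genotype"].isin(GENOTYPE_CLASSES)
        if bad.any():
            raise PedmapError(f"invalid genotype class {df.loc[bad, 'genotype'].iloc[0]!r}")
        if df["individual"].duplicated().any():
            dup = df.loc[df["individual"].duplicated(), "individual"].iloc[0]
            raise PedmapError(f"duplicate individual {dup!r} in variant table")
        self.table = df.reset_index(drop=True)

    def genotype_of(self, iid: str) -> str | None:
        sub = self.table.loc[self.table["individual"] == iid, "genotype"]
        return None if sub.empty else sub.iloc[0]

    def counts(self) -> dict[str, int]:
        c = self.table["genotype"].value_counts()
        return {g: int(c.get(g, 0)) for g in GENOTYPE_CLASSES}

    def genotype_label(self, cls: str) -> str:
        """Human-readable allele form, e.g. 'G/A' for het."""
        return {
            "hom_ref": f"{self.ref}/{self.ref}",
            "het": f"{self.ref}/{self.alt}",
            "hom_alt": f"{self.alt}/{self.alt}",
            "missing": "./.",
        }[cls]


def normalise_genotype_string(raw: str, ref: str, alt: str) -> str | None:
    """Map an allele-pair string onto a genotype class.

    Accepts '/'-, '|'- or whitespace-separated unordered pairs ("G/A" and
    "A/G" are the same genotype). Returns ``None`` for unrecognisable input
    so callers can warn and record a missing call.
    """
    txt = raw.strip()
    if txt in {"", ".", "./.", ".|.", "NA", "-"}:
        return "missing"
    for sep in ("/", "|"):
        txt = txt.replace(sep, " ")
    parts = txt.split()
    if len(parts) != 2:
        return None
    pair = frozenset(parts)
    if pair == {ref}:
        return "hom_ref"
    if pair == {alt}:
        return "hom_alt"
    if pair == {ref, alt}:
        return "het"
    return None
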