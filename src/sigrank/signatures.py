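"""Gene-signature and mutation-annotation IO.

Reads signatures from GMT files (one tab-separated set per line) or
MSigDB-style XML (GENESET records, member IDs taken from a chosen
attribute), pairs ``_UP``/``_DN``-suffixed sets into bidirectional
signatures, and parses curated mutation-call tables into boolean
per-patient flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .scoring import GeneSignature

__all__ = [
    "MutationTable",
    "read_signatures",
    "write_gmt",
    "pair_directional_sets",
    "parse_curated_mutations",
    "join_samples_to_patients",
]

#: Curated mutation columns and the literal (case-sensitive) substrings
#: that call each lesion from the source table.
MUTATION_CRITERIA = {
    "NPM1c.Mut": ("NPM1", ("p.W287fs", "p.W288fs")),
    "KMT2A.Fusion": ("MLL-partner", ("MLL-", "-MLL")),
    "KMT2A.PTD": ("MLL-PTD", ("exons",)),
    "PML.RARA": ("PML-RARA", ("PML-RARA",)),
}


@dataclass
class MutationTable:
    """Boolean mutation-status flags per patient (absent evidence = False)."""

    table: pd.DataFrame  # index patient_id; boolean columns per lesion

    def __post_init__(self):
        if self.table.index.duplicated().any():
            raise ValueError("duplicated patient IDs in mutation table")
        self.table = self.table.fillna(False).astype(bool)

    @property
    def patient_ids(self) -> pd.Index:
        return self.table.index

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="patient_id")

    @classmethod
    def from_tsv(cls, path) -> "MutationTable":
        return cls(pd.read_csv(path, sep="\t", index_col="patient_id"))


def _read_gmt(path: Path) -> list[tuple[str, list[str]]]:
    sets = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}: GMT line needs name, description and >=1 gene: {line!r}"
            )
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise ValueError(f"{path}: empty gene set {name!r}")
        sets.append((name, genes))
    return sets


def _read_msigdb_xml(path: Path, id_field: str) -> list[tuple[str, list[str]]]:
    from lxml import etree

    tree = etree.parse(str(path))
    sets = []
    for rec in tree.iter("GENESET"):
        name = rec.get("STANDARD_NAME")
        members = rec.get(id_field)
        if name is None or members is None:
            raise ValueError(
                f"{path}: GENESET record lacks STANDARD_NAME or {id_field}"
            )
        genes = [g for g in members.split(",") if g]
        if not genes:
            raise ValueError(f"{path}: empty gene set {name!r}")
        sets.append((name, genes))
    return sets


def read_signatures(
    paths: Sequence, fmt: str = "gmt", id_field: str = "MEMBERS_EZID"
) -> list[tuple[str, list[str]]]:
    """Read named gene sets from one or more GMT or MSigDB XML files.

    Order of sets follows file order; duplicate set names across the
    collection are an error.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    collection: list[tuple[str, list[str]]] = []
    for p in paths:
        p = Path(p)
        if fmt == "gmt":
            collection.extend(_read_gmt(p))
        elif fmt == "msigdb_xml":
            collection.extend(_read_msigdb_xml(p, id_field))
        else:
            raise ValueError(f"unknown signature format: {fmt!r}")
    names = [n for n, _ in collection]
    dups = {n for n in names if names.count(n) > 1}
    if dups:
        raise ValueError(f"duplicate gene-set names: {sorted(dups)}")
    return collection


def write_gmt(collection: Iterable[tuple[str, Sequence[str]]], path) -> None:
    """Write named gene sets as GMT (description column left generic)."""
    lines = [
        "\t".join([name, "na", *map(str, genes)]) for name, genes in collection
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def pair_directional_sets(
    collection: Sequence[tuple[str, Sequence[str]]],
    unpaired_mode: str = "unknown_direction",
    require_pairs: bool = False,
) -> list[GeneSignature]:
    """Pair ``<base>_UP`` / ``<base>_DN`` sets into bidirectional signatures.

    Sets without a partner become single-direction or unknown-direction
    signatures according to ``unpaired_mode`` (``_UP``/``_DN`` suffixes
    still set the direction for ``single`` mode).  With
    ``require_pairs=True`` an unpaired directional set is an error.
    """
    by_name = {name: list(genes) for name, genes in collection}
    if len(by_name) != len(collection):
        raise ValueError("duplicate set names in collection")
    used: set[str] = set()
    signatures: list[GeneSignature] = []
    for name, genes in collection:
        if name in used:
            continue
        base = None
        if name.endswith("_UP"):
            base, partner = name[:-3], name[:-3] + "_DN"
        elif name.endswith("_DN"):
            base, partner = name[:-3], name[:-3] + "_UP"
        if base is not None and partner in by_name:
            up = by_name[name] if name.endswith("_UP") else by_name[partner]
            dn = by_name[partner] if name.endswith("_UP") else by_name[name]
            signatures.append(
                GeneSignature(name=base, up_ids=tuple(up), down_ids=tuple(dn), mode="paired")
            )
            used.update({name, partner})
            continue
        if base is not None and require_pairs:
            raise ValueError(f"directional set {name!r} has no partner")
        if name.endswith("_UP"):
            mode = "single_directed_up"
        elif name.endswith("_DN"):
            mode = "single_directed_down"
        else:
            mode = unpaired_mode
        up = tuple(genes) if mode != "single_directed_down" else ()
        dn = tuple(genes) if mode == "single_directed_down" else ()
        signatures.append(GeneSignature(name=name, up_ids=up, down_ids=dn, mode=mode))
        used.add(name)
    return signatures


def parse_curated_mutations(table: pd.DataFrame, patient_col: str = "TCGA Patient ID") -> MutationTable:
    """Derive boolean mutation flags from a curated clinical table.

    A lesion is called when its source column contains one of the
    literal substrings in :data:`MUTATION_CRITERIA` (case-sensitive);
    empty or missing cells yield False.
    """
    if patient_col not in table.columns:
        raise ValueError(f"missing required column: {patient_col!r}")
    out = {}
    for flag, (col, needles) in MUTATION_CRITERIA.items():
        if col not in table.columns:
            raise ValueError(f"missing required column: {col!r}")
        cells = table[col].fillna("").astype(str)
        out[flag] = cells.map(lambda s: any(n in s for n in needles))
    df = pd.DataFrame(out)
    df.index = table[patient_col].astype(str)
    df.index.name = "patient_id"
    return MutationTable(df)


def join_samples_to_patients(
    sample_ids: Sequence[str], mutations: MutationTable, prefix_len: int = 12
) -> pd.DataFrame:
    """Annotate samples with patient mutation flags via barcode prefix.

    TCGA-style sample barcodes map to patients by their first
    ``prefix_len`` characters.  Samples without a matching patient are
    reported in a warning and carry all-False flags, never silently
    dropped.
    """
    patients = [str(s)[:prefix_len] for s in sample_ids]
    unmatched = sorted({p for p in patients if p not in mutations.table.index})
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} sample barcodes have no mutation annotation: "
            + ", ".join(unmatched),
            stacklevel=2,
        )
    rows = mutations.table.reindex(patients, fill_value=False).astype(bool)
    rows.index = pd.Index(sample_ids, name="sample_id")
    return rows
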