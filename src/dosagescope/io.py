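"""Readers, writers and validated containers for every external artifact.

All tabular artifacts are plain text (TSV) with a ``.`` decimal separator;
karyotype configs are YAML or JSON; gene sets use the GMT convention.
Replicate structure lives only in the sample sheet, never inside the
expression matrix itself.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "SampleSheet",
    "GeneAnnotation",
    "Karyotype",
    "GeneSetCollection",
    "normalize_chromosome",
    "read_expression",
    "write_expression",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotation",
    "write_annotation",
    "read_karyotypes",
    "write_karyotypes",
    "read_gene_sets",
    "write_gene_sets",
]


def normalize_chromosome(name: object) -> str:
    """Canonical chromosome identifier: case-insensitive ``chr`` prefix
    stripped, leading zeros removed from purely numeric names.

    ``Chr11``, ``chr11``, ``11`` and ``Chr011`` all map to ``"11"``.
    The mapping is idempotent.
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.isdigit():
        s = str(int(s))
    return s


class SampleSheet:
    """Binding of sequencing samples to strains and replicate indices.

    Parameters
    ----------
    table
        DataFrame with columns ``sample_id``, ``strain_id``, ``replicate``
        (positive integers).
    """

    REQUIRED = ("sample_id", "strain_id", "replicate")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        table = table.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        table["sample_id"] = table["sample_id"].astype(str)
        table["strain_id"] = table["strain_id"].astype(str)
        table["replicate"] = table["replicate"].astype(int)
        if (table["replicate"] < 1).any():
            raise ValueError("replicate indices must be positive integers")
        dup = table["sample_id"][table["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
        pairs = table[["strain_id", "replicate"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            raise ValueError("duplicate (strain_id, replicate) pairs in sample sheet")
        self.table = table

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.table["strain_id"]))

    def samples_for(self, strain_id: str) -> list[str]:
        sub = self.table[self.table["strain_id"] == strain_id]
        if sub.empty:
            raise KeyError(f"strain {strain_id!r} not in sample sheet")
        return list(sub.sort_values("replicate")["sample_id"])

    def __contains__(self, strain_id: str) -> bool:
        return strain_id in set(self.table["strain_id"])

    def __repr__(self) -> str:
        return f"SampleSheet({len(self.table)} samples, {len(self.strains)} strains)"


class ExpressionMatrix:
    """Gene-by-sample matrix of nonnegative FPKM-like values."""

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dups = sorted(set(values.index[values.index.duplicated()]))
            raise ValueError(f"duplicated gene ids: {dups[:5]}")
        if values.columns.duplicated().any():
            raise ValueError("duplicated sample ids in expression matrix")
        arr = values.to_numpy(dtype=float, copy=False)
        bad = ~np.isfinite(arr) | (arr < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "invalid expression value at "
                f"(gene={values.index[i]!r}, sample={values.columns[j]!r}): "
                f"{values.iat[i, j]!r} (must be finite and >= 0)"
            )
        self.values = values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        self.values.index.name = "gene_id"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"


class GeneAnnotation:
    """Gene → chromosome map over a declared chromosome universe.

    Chromosome names are normalized with :func:`normalize_chromosome`.
    """

    def __init__(
        self,
        mapping: Mapping[str, str],
        chromosomes: Iterable[str] | None = None,
    ):
        self._map = {str(g): normalize_chromosome(c) for g, c in mapping.items()}
        if chromosomes is not None:
            universe = {normalize_chromosome(c) for c in chromosomes}
            stray = set(self._map.values()) - universe
            if stray:
                raise ValueError(f"chromosomes outside declared universe: {sorted(stray)}")
        else:
            universe = set(self._map.values())
        self.chromosomes = universe

    def chromosome_of(self, gene_id: str) -> str:
        return self._map[gene_id]

    @property
    def genes(self) -> list[str]:
        return list(self._map)

    def genes_on(self, chromosome: str) -> frozenset[str]:
        c = normalize_chromosome(chromosome)
        return frozenset(g for g, ch in self._map.items() if ch == c)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    def __repr__(self) -> str:
        return f"GeneAnnotation({len(self)} genes, {len(self.chromosomes)} chromosomes)"


@dataclass(frozen=True)
class Karyotype:
    """Copy-number description of one strain: which chromosomes are carried
    in an extra copy on top of the disomic baseline.  An empty extra set
    marks a euploid strain (wild type, or offspring that regained 2n)."""

    strain_id: str
    extra_chromosomes: frozenset[str] = field(default_factory=frozenset)
    baseline_copy_number: int = 2

    @property
    def is_euploid(self) -> bool:
        return not self.extra_chromosomes


class GeneSetCollection:
    """Named, non-empty gene sets (functional groups, pathway terms, ...)."""

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ):
        self._sets: dict[str, frozenset[str]] = {}
        for name, genes in sets.items():
            fs = frozenset(str(g) for g in genes)
            if not fs:
                raise ValueError(f"gene set {name!r} is empty")
            self._sets[str(name)] = fs
        self.descriptions = dict(descriptions or {})

    def __getitem__(self, name: str) -> frozenset[str]:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def items(self):
        return self._sets.items()

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets)"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    # TSV is the native format; fall back to comma if no tabs in header.
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_expression(path: str | Path, sample_sheet: SampleSheet) -> ExpressionMatrix:
    """Read a gene-by-sample expression table (first column gene ids,
    header row sample ids) and validate it against the sample sheet."""
    raw = _read_table(path)
    gene_col = raw.columns[0]
    genes = raw[gene_col].astype(str)
    if genes.duplicated().any():
        dups = sorted(set(genes[genes.duplicated()]))
        raise ValueError(f"duplicated gene ids in {path}: {dups[:5]}")
    known = set(sample_sheet.sample_ids)
    for s in raw.columns[1:]:
        if s not in known:
            raise ValueError(f"sample {s!r} in {path} is absent from the sample sheet")
    values = raw.set_index(gene_col)
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value at (gene={values.index[i]!r}, "
            f"sample={values.columns[j]!r}): {values.iat[i, j]!r}"
        )
    return ExpressionMatrix(numeric)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(_read_table(path))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def _parse_gff3_genes(path: Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            seqid, _, ftype = fields[0], fields[1], fields[2]
            if ftype != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID")
            if gid is None:
                raise ValueError(f"{path}:{lineno}: gene feature without ID attribute")
            _record_gene(mapping, gid, seqid, f"{path}:{lineno}")
    return mapping


def _record_gene(mapping: dict[str, str], gene: str, chrom: str, where: str) -> None:
    c = normalize_chromosome(chrom)
    prev = mapping.get(gene)
    if prev is not None and prev != c:
        raise ValueError(f"{where}: gene {gene!r} assigned to both {prev!r} and {c!r}")
    mapping[gene] = c


def read_annotation(
    path: str | Path,
    format: str | None = None,
    chromosomes: Iterable[str] | None = None,
) -> GeneAnnotation:
    """Read a gene→chromosome annotation.

    ``format`` is ``"gff3"`` or ``"tsv"``; when omitted it is inferred from
    the file extension (``.gff``/``.gff3`` → GFF3, otherwise two-column TSV).
    """
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "tsv"
    if format == "gff3":
        mapping = _parse_gff3_genes(path)
    elif format == "tsv":
        mapping = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                gene, chrom = fields[0], fields[1]
                if lineno == 1 and gene.lower() in {"gene_id", "gene"}:
                    continue  # optional header
                _record_gene(mapping, gene, chrom, f"{path}:{lineno}")
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return GeneAnnotation(mapping, chromosomes=chromosomes)


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchromosome\n")
        for gene, chrom in annotation.items():
            fh.write(f"{gene}\t{chrom}\n")


def read_karyotypes(
    path: str | Path,
    universe: Iterable[str] | GeneAnnotation | None = None,
) -> dict[str, Karyotype]:
    """Read a strain → extra-chromosome config (YAML or JSON mapping).

    When ``universe`` (an iterable of chromosome names or a
    :class:`GeneAnnotation`) is given, extra chromosomes outside it raise.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: expected a mapping of strain -> extra chromosomes")
    if isinstance(universe, GeneAnnotation):
        universe = universe.chromosomes
    allowed = None if universe is None else {normalize_chromosome(c) for c in universe}
    out: dict[str, Karyotype] = {}
    for strain, extras in raw.items():
        extras = extras or []
        norm = frozenset(normalize_chromosome(c) for c in extras)
        if allowed is not None:
            stray = norm - allowed
            if stray:
                raise ValueError(
                    f"strain {strain!r}: extra chromosomes {sorted(stray)} "
                    "not in the annotated chromosome universe"
                )
        out[str(strain)] = Karyotype(str(strain), norm)
    return out


def write_karyotypes(karyotypes: Mapping[str, Karyotype], path: str | Path) -> None:
    doc = {k.strain_id: sorted(k.extra_chromosomes) for k in karyotypes.values()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>gene...``.

    Duplicate genes within a line are deduplicated; a line with fewer than
    three fields (i.e. an empty set) is a parse error.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(g for g in genes if g)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")
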