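"""Readers and writers for every tabular artifact the pipeline touches.

All files are UTF-8 TSV with a header row; lines starting with ``#`` are
ignored. Readers validate strictly and raise :class:`GenioError` rather than
coerce malformed input; every writer/reader pair is an inverse on valid data.

Two genotype dialects are supported: a plain sample-by-SNP matrix of counted
allele copies, and PLINK PED/MAP. Reference allele-frequency tables follow a
fixed HapMap-style column layout (SNP identity, alleles, strand, counted
allele, frequency, number of alleles sampled).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
MISSING_CODE = -1  #: internal genotype sentinel
MISSING_TOKEN = "NA"  #: on-disk genotype sentinel

REF_FREQ_COLUMNS = [
    "snp_id",
    "chromosome",
    "position",
    "allele_a",
    "allele_b",
    "strand",
    "counted_allele",
    "paf",
    "n_alleles",
]


class GenioError(ValueError):
    """Malformed input file or inconsistent table."""


@dataclass(frozen=True)
class SnpRecord:
    """Identity, position, allele pair, strand and counted allele of one array SNP.

    The allele pair is unordered; it is stored canonically with
    ``allele_a < allele_b`` (alphabetical). ``counted_allele`` is the allele
    whose copies the genotype codes and allele frequencies count.
    """

    snp_id: str
    chromosome: str
    position: int
    allele_a: str
    allele_b: str
    strand: str
    counted_allele: str

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise GenioError("snp_id must be non-empty")
        if self.position < 1:
            raise GenioError(f"{self.snp_id}: position must be 1-based positive, got {self.position}")
        for allele in (self.allele_a, self.allele_b):
            if allele not in VALID_BASES:
                raise GenioError(f"{self.snp_id}: invalid allele {allele!r}")
        if self.allele_a == self.allele_b:
            raise GenioError(f"{self.snp_id}: allele pair must contain two distinct bases")
        if self.allele_a > self.allele_b:  # canonicalize
            first, second = self.allele_b, self.allele_a
            object.__setattr__(self, "allele_a", first)
            object.__setattr__(self, "allele_b", second)
        if self.strand not in {"+", "-"}:
            raise GenioError(f"{self.snp_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.counted_allele not in (self.allele_a, self.allele_b):
            raise GenioError(
                f"{self.snp_id}: counted allele {self.counted_allele!r} not in pair "
                f"{{{self.allele_a},{self.allele_b}}}"
            )

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.allele_a, self.allele_b))

    @property
    def other_allele(self) -> str:
        return self.allele_b if self.counted_allele == self.allele_a else self.allele_a

    def complemented(self) -> "SnpRecord":
        """The same SNP encoded on the opposite strand."""
        return replace(
            self,
            allele_a=COMPLEMENT[self.allele_a],
            allele_b=COMPLEMENT[self.allele_b],
            strand="-" if self.strand == "+" else "+",
            counted_allele=COMPLEMENT[self.counted_allele],
        )


@dataclass
class GenotypeTable:
    """Samples x SNPs diploid genotype codes.

    ``codes[i, j]`` counts copies (0/1/2) of the counted allele of SNP ``j``
    in sample ``i``; missing genotypes are ``MISSING_CODE``.
    """

    sample_ids: list
    snp_ids: list
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n_samples, n_snps = self.codes.shape
        if len(self.sample_ids) != n_samples or len(self.snp_ids) != n_snps:
            raise GenioError("genotype table dimensions inconsistent with ids")
        if len(set(self.sample_ids)) != n_samples:
            raise GenioError("duplicate sample id in genotype table")
        if len(set(self.snp_ids)) != n_snps:
            raise GenioError("duplicate SNP id in genotype table")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING_CODE))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenioError(
                f"invalid genotype code {self.codes[i, j]} at sample "
                f"{self.sample_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        return self.codes[:, self.snp_ids.index(snp_id)]

    def subset_snps(self, keep: Sequence[str]) -> "GenotypeTable":
        idx = [self.snp_ids.index(s) for s in keep]
        return GenotypeTable(list(self.sample_ids), list(keep), self.codes[:, idx])

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return GenotypeTable(list(keep), list(self.snp_ids), self.codes[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.sample_ids, columns=self.snp_ids)


@dataclass
class GroupMapping:
    """Functional-group mapping: group id -> gene symbols, gene -> SNP ids."""

    group_to_genes: dict
    gene_to_snps: dict

    def __post_init__(self) -> None:
        for group, genes in self.group_to_genes.items():
            if not str(group):
                raise GenioError("empty group label")
            if not genes:
                raise GenioError(f"group {group!r} lists no genes")

    @property
    def groups(self) -> list:
        return list(self.group_to_genes)

    def snps_in_group(self, group) -> list:
        seen = []
        for gene in self.group_to_genes[group]:
            seen.extend(self.gene_to_snps.get(gene, ()))
        return seen

    def all_grouped_snps(self) -> set:
        out = set()
        for group in self.group_to_genes:
            out.update(self.snps_in_group(group))
        return out


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise GenioError(f"{path}: cannot parse TSV: {exc}") from exc


# ---------------------------------------------------------------------------
# SNP tables


def write_snp_table(records: Iterable[SnpRecord], path) -> None:
    rows = [
        (r.snp_id, r.chromosome, r.position, r.allele_a, r.allele_b, r.strand, r.counted_allele)
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["snp_id", "chromosome", "position", "allele_a", "allele_b", "strand", "counted_allele"],
    ).to_csv(path, sep="\t", index=False)


def read_snp_table(path) -> list:
    df = _read_tsv(path)
    required = {"snp_id", "chromosome", "position", "allele_a", "allele_b", "strand", "counted_allele"}
    if not required.issubset(df.columns):
        raise GenioError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise GenioError(f"{path}: duplicated snp_id {dup!r}")
    records = []
    for row in df.itertuples(index=False):
        try:
            position = int(row.position)
        except ValueError as exc:
            raise GenioError(f"{path}: non-integer position {row.position!r} for {row.snp_id}") from exc
        records.append(
            SnpRecord(row.snp_id, row.chromosome, position, row.allele_a, row.allele_b, row.strand, row.counted_allele)
        )
    return records


# ---------------------------------------------------------------------------
# Genotype matrix (TSV dialect)


def write_genotype_table(table: GenotypeTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\t" + "\t".join(table.snp_ids) + "\n")
        for sample, row in zip(table.sample_ids, table.codes):
            cells = [MISSING_TOKEN if c == MISSING_CODE else str(int(c)) for c in row]
            fh.write(str(sample) + "\t" + "\t".join(cells) + "\n")


def read_genotype_table(path, snp_table: Sequence[SnpRecord] | None = None) -> GenotypeTable:
    """Parse a sample-by-SNP genotype matrix.

    When ``snp_table`` is given, header SNP ids must all resolve against it.
    """
    df = _read_tsv(path)
    if df.columns[0] != "sample_id":
        raise GenioError(f"{path}: first column must be 'sample_id'")
    snp_ids = list(df.columns[1:])
    if snp_table is not None:
        known = {r.snp_id for r in snp_table}
        unknown = [s for s in snp_ids if s not in known]
        if unknown:
            raise GenioError(f"{path}: unknown SNP ids {unknown[:5]}")
    sample_ids = df["sample_id"].tolist()
    codes = np.full((len(sample_ids), len(snp_ids)), MISSING_CODE, dtype=np.int8)
    for j, snp in enumerate(snp_ids):
        for i, cell in enumerate(df[snp]):
            if cell == MISSING_TOKEN:
                continue
            if cell not in {"0", "1", "2"}:
                raise GenioError(
                    f"{path}: malformed genotype {cell!r} at sample {sample_ids[i]!r}, SNP {snp!r}"
                )
            codes[i, j] = int(cell)
    return GenotypeTable(sample_ids, snp_ids, codes)


# ---------------------------------------------------------------------------
# Genotype matrix (PLINK PED/MAP dialect)


def write_ped_map(table: GenotypeTable, snp_table: Sequence[SnpRecord], ped_path, map_path) -> None:
    by_id = {r.snp_id: r for r in snp_table}
    order = [by_id[s] for s in table.snp_ids]
    with open(map_path, "w", encoding="utf-8") as fh:
        for rec in order:
            fh.write(f"{rec.chromosome}\t{rec.snp_id}\t0\t{rec.position}\n")
    with open(ped_path, "w", encoding="utf-8") as fh:
        for sample, row in zip(table.sample_ids, table.codes):
            fields = [str(sample), str(sample), "0", "0", "0", "-9"]
            for rec, code in zip(order, row):
                if code == MISSING_CODE:
                    fields += ["0", "0"]
                else:
                    fields += [rec.counted_allele] * int(code) + [rec.other_allele] * (2 - int(code))
            fh.write(" ".join(fields) + "\n")


def read_ped_map(ped_path, map_path, snp_table: Sequence[SnpRecord]) -> GenotypeTable:
    """Parse a PLINK PED/MAP pair into counted-allele copy codes."""
    by_id = {r.snp_id: r for r in snp_table}
    snp_ids = []
    with open(map_path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise GenioError(f"{map_path}: MAP line needs 4 fields: {line.rstrip()!r}")
            snp_id = parts[1]
            if snp_id not in by_id:
                raise GenioError(f"{map_path}: unknown SNP id {snp_id!r}")
            snp_ids.append(snp_id)
    sample_ids, rows = [], []
    with open(ped_path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * len(snp_ids):
                raise GenioError(
                    f"{ped_path}: expected {6 + 2 * len(snp_ids)} fields, got {len(parts)}"
                )
            sample = parts[1]
            if sample in sample_ids:
                raise GenioError(f"{ped_path}: duplicate sample id {sample!r}")
            sample_ids.append(sample)
            row = np.full(len(snp_ids), MISSING_CODE, dtype=np.int8)
            for j, snp_id in enumerate(snp_ids):
                a1, a2 = parts[6 + 2 * j], parts[7 + 2 * j]
                if a1 == "0" or a2 == "0":
                    continue
                rec = by_id[snp_id]
                for allele in (a1, a2):
                    if allele not in rec.alleles:
                        raise GenioError(
                            f"{ped_path}: sample {sample!r}, SNP {snp_id!r}: allele {allele!r} "
                            f"not in pair {{{rec.allele_a},{rec.allele_b}}}"
                        )
                row[j] = (a1 == rec.counted_allele) + (a2 == rec.counted_allele)
            rows.append(row)
    return GenotypeTable(sample_ids, snp_ids, np.array(rows, dtype=np.int8))


# ---------------------------------------------------------------------------
# Reference allele-frequency tables


def write_reference_frequencies(frame: pd.DataFrame, path) -> None:
    frame.loc[:, REF_FREQ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_reference_frequencies(path) -> pd.DataFrame:
    """Parse a HapMap-style per-SNP allele-frequency table.

    Returns a DataFrame with :data:`REF_FREQ_COLUMNS`; ``paf`` is the
    proportion of the counted allele and ``n_alleles`` the (even) number of
    alleles sampled.
    """
    df = _read_tsv(path)
    missing = [c for c in REF_FREQ_COLUMNS if c not in df.columns]
    if missing:
        raise GenioError(f"{path}: missing columns {missing}")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise GenioError(f"{path}: duplicated snp_id {dup!r}")
    out = df.loc[:, REF_FREQ_COLUMNS].copy()
    try:
        out["position"] = out["position"].astype(int)
        out["paf"] = out["paf"].astype(float)
        out["n_alleles"] = out["n_alleles"].astype(int)
    except ValueError as exc:
        raise GenioError(f"{path}: non-numeric frequency fields: {exc}") from exc
    bad_freq = out[(out["paf"] < 0) | (out["paf"] > 1)]
    if len(bad_freq):
        raise GenioError(f"{path}: frequency outside [0,1] for {bad_freq['snp_id'].iloc[0]!r}")
    bad_n = out[(out["n_alleles"] < 2) | (out["n_alleles"] % 2 != 0)]
    if len(bad_n):
        raise GenioError(f"{path}: n_alleles must be even and >=2 for {bad_n['snp_id'].iloc[0]!r}")
    # validates allele fields through the record constructor
    for row in out.itertuples(index=False):
        SnpRecord(row.snp_id, row.chromosome, int(row.position), row.allele_a, row.allele_b, row.strand, row.counted_allele)
    return out.reset_index(drop=True)


def reference_records(frame: pd.DataFrame) -> dict:
    """SnpRecord per snp_id from a reference-frequency frame."""
    return {
        row.snp_id: SnpRecord(
            row.snp_id, row.chromosome, int(row.position), row.allele_a, row.allele_b, row.strand, row.counted_allele
        )
        for row in frame.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# Group mapping


def write_group_mapping(mapping: GroupMapping, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group\tgene\tsnp_id\n")
        for group, genes in mapping.group_to_genes.items():
            for gene in genes:
                snps = mapping.gene_to_snps.get(gene, [])
                if not snps:
                    fh.write(f"{group}\t{gene}\t{MISSING_TOKEN}\n")
                for snp in snps:
                    fh.write(f"{group}\t{gene}\t{snp}\n")


def read_group_mapping(path) -> GroupMapping:
    """Parse a three-column (group, gene, snp_id) TSV into a GroupMapping.

    A gene listed under two groups is retained in both; multiplicities of the
    (group, gene) pairs are preserved in order of first appearance.
    """
    df = _read_tsv(path)
    for col in ("group", "gene", "snp_id"):
        if col not in df.columns:
            raise GenioError(f"{path}: missing column {col!r}")
    group_to_genes: dict = {}
    gene_to_snps: dict = {}
    for row in df.itertuples(index=False):
        if not row.group:
            raise GenioError(f"{path}: empty group label")
        genes = group_to_genes.setdefault(row.group, [])
        if row.gene not in genes:
            genes.append(row.gene)
        snps = gene_to_snps.setdefault(row.gene, [])
        if row.snp_id != MISSING_TOKEN and row.snp_id not in snps:
            snps.append(row.snp_id)
    return GroupMapping(group_to_genes, gene_to_snps)
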