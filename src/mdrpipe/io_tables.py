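"""Genotype and phenotype table containers and their on-disk dialects.

All downstream stages consume only the in-memory types defined here:

* :class:`GenotypeMatrix` — samples x SNPs of unordered biallelic calls,
  stored internally as the count of the lexicographically later allele
  (0, 1, 2) with ``-1`` for missing.
* :class:`PhenotypeTable` — case/control status, an optional binary
  sub-phenotype (e.g. coronary-artery-lesion formation, defined only for
  cases), and any number of non-negative continuous biomarker columns.

Two genotype dialects are supported: a one-row-per-sample TSV whose header
cells carry the SNP metadata (``snp_id|gene|alleles|category``), and
PLINK-style text ``.ped``/``.map`` pairs ("0 0" = missing call).  Within a
call the allele order is non-informative (genotypes are unphased); the
canonical serialized order is lexicographic, so ``("G", "A")`` is written
``"AG"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1
MISSING_TOKEN = "NN"
CATEGORIES = ("innate", "adaptive", "stress")


class ParseError(ValueError):
    """Malformed input file (names the offending line where possible)."""


class ValidationError(ValueError):
    """In-memory table violates a container invariant."""


@dataclass(frozen=True)
class SnpMeta:
    """Metadata for one biallelic SNP.

    ``allele_a`` < ``allele_b`` lexicographically; genotype codes count
    copies of ``allele_b``.  ``category`` mirrors the three candidate-gene
    panel sections (innate / adaptive immunity, stress and response).
    """

    snp_id: str
    allele_a: str
    allele_b: str
    gene: str = "."
    category: str | None = None

    def __post_init__(self) -> None:
        if len(self.allele_a) != 1 or len(self.allele_b) != 1:
            raise ValidationError(f"{self.snp_id}: alleles must be single characters")
        if self.allele_a == self.allele_b:
            raise ValidationError(f"{self.snp_id}: allele_a and allele_b must differ")
        if self.allele_a > self.allele_b:
            raise ValidationError(
                f"{self.snp_id}: alleles must be lexicographically ordered "
                f"({self.allele_a!r} > {self.allele_b!r})"
            )
        if self.category is not None and self.category not in CATEGORIES:
            raise ValidationError(
                f"{self.snp_id}: category {self.category!r} not in {CATEGORIES}"
            )

    def call_str(self, code: int) -> str:
        """Canonical two-character genotype string for a code (missing -> token)."""
        if code == MISSING:
            return MISSING_TOKEN
        if code == 0:
            return self.allele_a * 2
        if code == 1:
            return self.allele_a + self.allele_b
        if code == 2:
            return self.allele_b * 2
        raise ValueError(f"invalid genotype code {code}")


def _code_from_call(call: str, meta: SnpMeta, sample_id: str) -> int:
    pair = sorted(call)
    for ch in pair:
        if ch not in (meta.allele_a, meta.allele_b):
            raise ValidationError(
                f"SNP {meta.snp_id}, sample {sample_id}: allele {ch!r} outside "
                f"declared pair {meta.allele_a}/{meta.allele_b} (call {call!r})"
            )
    return pair.count(meta.allele_b)


@dataclass
class GenotypeMatrix:
    """Unordered biallelic genotype calls for ``n_samples`` x ``n_snps``.

    ``codes[i, j]`` counts copies of ``snps[j].allele_b`` in sample ``i``
    (0/1/2) or is :data:`MISSING`.
    """

    sample_ids: list[str]
    snps: list[SnpMeta]
    codes: np.ndarray  # int8, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample ids are not unique")
        ids = [m.snp_id for m in self.snps]
        if len(set(ids)) != len(ids):
            raise ValidationError("snp ids are not unique")
        if self.codes.shape != (len(self.sample_ids), len(self.snps)):
            raise ValidationError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} snps"
            )
        bad = (self.codes < MISSING) | (self.codes > 2)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"invalid genotype code {self.codes[i, j]} at sample "
                f"{self.sample_ids[i]}, snp {self.snps[j].snp_id}"
            )

    # -- accessors ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [m.snp_id for m in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown snp_id {snp_id!r}") from None

    def call_str(self, i: int, j: int) -> str:
        return self.snps[j].call_str(int(self.codes[i, j]))

    def subset_snps(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snps=[self.snps[int(j)] for j in keep],
            codes=self.codes[:, keep].copy(),
        )

    def subset_samples(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[int(i)] for i in keep],
            snps=list(self.snps),
            codes=self.codes[keep, :].copy(),
        )

    @classmethod
    def from_calls(
        cls,
        sample_ids: Sequence[str],
        snps: Sequence[SnpMeta],
        calls: Iterable[Sequence[str | None]],
    ) -> "GenotypeMatrix":
        """Build from two-character call strings (``None`` or token = missing)."""
        codes = np.full((len(sample_ids), len(snps)), MISSING, dtype=np.int8)
        for i, row in enumerate(calls):
            for j, call in enumerate(row):
                if call is None or call == MISSING_TOKEN:
                    continue
                codes[i, j] = _code_from_call(call, snps[j], sample_ids[i])
        return cls(list(sample_ids), list(snps), codes)


@dataclass
class PhenotypeTable:
    """Per-sample outcome(s) and biomarker concentrations.

    ``status``: 1 = case, 0 = control.  ``cal`` is a binary sub-phenotype
    defined only for cases (NaN elsewhere).  ``biomarkers`` is a DataFrame
    indexed by sample id, non-negative values in pg/ml, NaN where missing.
    """

    sample_ids: list[str]
    status: np.ndarray
    cal: np.ndarray = field(default=None)  # type: ignore[assignment]
    biomarkers: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int64)
        n = len(self.sample_ids)
        if self.cal is None:
            self.cal = np.full(n, np.nan)
        self.cal = np.asarray(self.cal, dtype=float)
        if self.biomarkers is None:
            self.biomarkers = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        self.validate()

    def validate(self) -> None:
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample ids are not unique")
        if self.status.shape != (n,) or not np.isin(self.status, [0, 1]).all():
            raise ValidationError("status must be a binary (0/1) vector, one per sample")
        if self.cal.shape != (n,):
            raise ValidationError("cal length mismatch")
        has_cal = ~np.isnan(self.cal)
        if has_cal.any():
            if not np.isin(self.cal[has_cal], [0, 1]).all():
                raise ValidationError("cal must be binary where present")
            if (self.status[has_cal] != 1).any():
                i = int(np.flatnonzero(has_cal & (self.status == 0))[0])
                raise ValidationError(
                    f"cal set for control sample {self.sample_ids[i]}"
                )
        if list(self.biomarkers.index) != list(self.sample_ids):
            raise ValidationError("biomarker index must equal sample_ids")
        vals = self.biomarkers.to_numpy(dtype=float) if len(self.biomarkers.columns) else None
        if vals is not None and np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("biomarker values must be non-negative")

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())

    @property
    def biomarker_names(self) -> list[str]:
        return list(self.biomarkers.columns)

    def aligned_status(self, gm: GenotypeMatrix) -> np.ndarray:
        """Status vector reordered to match ``gm.sample_ids``."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in gm.sample_ids]
        except KeyError as exc:
            raise ValidationError(f"sample {exc.args[0]!r} has no phenotype row") from None
        return self.status[idx]


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def _header_cell(meta: SnpMeta) -> str:
    cat = meta.category if meta.category is not None else "."
    return f"{meta.snp_id}|{meta.gene}|{meta.allele_a}{meta.allele_b}|{cat}"


def _parse_header_cell(cell: str) -> tuple[str, str | None, str | None, str | None]:
    """Returns (snp_id, gene, alleles, category); bare snp ids are allowed."""
    if "|" not in cell:
        return cell, None, None, None
    parts = cell.split("|")
    if len(parts) != 4:
        raise ParseError(f"bad SNP header cell {cell!r} (want snp_id|gene|AB|category)")
    snp_id, gene, alleles, cat = parts
    if len(alleles) != 2:
        raise ParseError(f"bad allele pair {alleles!r} in header cell {cell!r}")
    return snp_id, gene, alleles, (None if cat == "." else cat)


_FALLBACK_ALLELES = "ACGT"


def _infer_meta(snp_id: str, column: list[str], missing_token: str) -> SnpMeta:
    chars: set[str] = set()
    for call in column:
        if call != missing_token:
            chars.update(call)
    if len(chars) > 2:
        raise ParseError(f"SNP {snp_id}: more than two alleles observed {sorted(chars)}")
    if len(chars) == 2:
        a, b = sorted(chars)
    elif len(chars) == 1:
        (a,) = chars
        b = next(c for c in _FALLBACK_ALLELES if c != a)
        a, b = sorted((a, b))
    else:
        a, b = "A", "C"
    return SnpMeta(snp_id=snp_id, allele_a=a, allele_b=b)


def write_genotypes(gm: GenotypeMatrix, path: str | Path, dialect: str = "tsv") -> None:
    """Serialize a genotype matrix; ``read_genotypes(write(...))`` is the identity."""
    if dialect == "tsv":
        _write_tsv(gm, Path(path))
    elif dialect == "pedmap":
        _write_pedmap(gm, Path(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_genotypes(
    path: str | Path, dialect: str = "tsv", missing_token: str = MISSING_TOKEN
) -> GenotypeMatrix:
    if dialect == "tsv":
        return _read_tsv(Path(path), missing_token)
    if dialect == "pedmap":
        return _read_pedmap(Path(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_tsv(gm: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id")
        for meta in gm.snps:
            fh.write("\t" + _header_cell(meta))
        fh.write("\n")
        for i, sid in enumerate(gm.sample_ids):
            cells = [gm.call_str(i, j) for j in range(gm.n_snps)]
            fh.write("\t".join([sid] + cells) + "\n")


def _read_tsv(path: Path, missing_token: str) -> GenotypeMatrix:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != "sample_id":
        raise ParseError(f"{path}:1: first column must be 'sample_id'")
    parsed = [_parse_header_cell(c) for c in header[1:]]
    n_snps = len(parsed)

    sample_ids: list[str] = []
    rows: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_snps + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {n_snps + 1} columns, got {len(fields)}"
            )
        sample_ids.append(fields[0])
        rows.append(fields[1:])

    snps: list[SnpMeta] = []
    for j, (snp_id, gene, alleles, cat) in enumerate(parsed):
        if alleles is None:
            snps.append(_infer_meta(snp_id, [r[j] for r in rows], missing_token))
        else:
            a, b = sorted(alleles)
            snps.append(SnpMeta(snp_id=snp_id, allele_a=a, allele_b=b,
                                gene=gene or ".", category=cat))

    codes = np.full((len(sample_ids), n_snps), MISSING, dtype=np.int8)
    for i, row in enumerate(rows):
        for j, call in enumerate(row):
            if call == missing_token:
                continue
            if len(call) != 2:
                raise ParseError(
                    f"{path}:{i + 2}: call {call!r} for snp {snps[j].snp_id} is not "
                    f"a two-character genotype or the missing token {missing_token!r}"
                )
            codes[i, j] = _code_from_call(call, snps[j], sample_ids[i])
    return GenotypeMatrix(sample_ids, snps, codes)


# ---------------------------------------------------------------------------
# PLINK-style text ped/map dialect
# ---------------------------------------------------------------------------

def _pedmap_prefix(path: Path) -> Path:
    return path.with_suffix("") if path.suffix in (".ped", ".map") else path


def _write_pedmap(gm: GenotypeMatrix, path: Path) -> None:
    prefix = _pedmap_prefix(path)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j, meta in enumerate(gm.snps):
            fh.write(f"1\t{meta.snp_id}\t0\t{j + 1}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j, meta in enumerate(gm.snps):
                code = int(gm.codes[i, j])
                if code == MISSING:
                    fields += ["0", "0"]
                else:
                    call = meta.call_str(code)
                    fields += [call[0], call[1]]
            fh.write(" ".join(fields) + "\n")
    # gene/category/declared alleles are not representable in ped/map; a small
    # sidecar keeps the round trip exact.
    with open(prefix.with_suffix(".snpinfo.tsv"), "w") as fh:
        fh.write("snp_id\tgene\tallele_a\tallele_b\tcategory\n")
        for meta in gm.snps:
            cat = meta.category if meta.category is not None else "."
            fh.write(f"{meta.snp_id}\t{meta.gene}\t{meta.allele_a}\t{meta.allele_b}\t{cat}\n")


def _read_pedmap(path: Path) -> GenotypeMatrix:
    prefix = _pedmap_prefix(path)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    if not map_path.exists():
        raise ParseError(f"missing map file {map_path}")
    if not ped_path.exists():
        raise ParseError(f"missing ped file {ped_path}")

    snp_ids: list[str] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 columns")
            snp_ids.append(fields[1])
    n_snps = len(snp_ids)

    sample_ids: list[str] = []
    raw_calls: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} columns, "
                    f"got {len(fields)}"
                )
            sample_ids.append(fields[1])
            raw_calls.append(
                [(fields[6 + 2 * j], fields[7 + 2 * j]) for j in range(n_snps)]
            )

    sidecar = prefix.with_suffix(".snpinfo.tsv")
    metas: dict[str, SnpMeta] = {}
    if sidecar.exists():
        df = pd.read_csv(sidecar, sep="\t", dtype=str)
        for _, row in df.iterrows():
            metas[row["snp_id"]] = SnpMeta(
                snp_id=row["snp_id"],
                allele_a=row["allele_a"],
                allele_b=row["allele_b"],
                gene=row["gene"],
                category=None if row["category"] == "." else row["category"],
            )

    snps: list[SnpMeta] = []
    for j, sid in enumerate(snp_ids):
        if sid in metas:
            snps.append(metas[sid])
        else:
            column = [
                "".join(sorted(pair)) if "0" not in pair else MISSING_TOKEN
                for pair in (rc[j] for rc in raw_calls)
            ]
            snps.append(_infer_meta(sid, column, MISSING_TOKEN))

    codes = np.full((len(sample_ids), n_snps), MISSING, dtype=np.int8)
    for i, rc in enumerate(raw_calls):
        for j, (a1, a2) in enumerate(rc):
            if a1 == "0" or a2 == "0":
                continue
            codes[i, j] = _code_from_call(a1 + a2, snps[j], sample_ids[i])
    return GenotypeMatrix(sample_ids, snps, codes)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

RESERVED_PHENO_COLS = ("sample_id", "status", "cal")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype TSV; extra numeric columns become biomarkers."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "status"):
        if col not in df.columns:
            raise ParseError(f"{path}: required column {col!r} missing")
    sample_ids = [str(s) for s in df["sample_id"]]
    status = df["status"].to_numpy()
    cal = df["cal"].to_numpy(dtype=float) if "cal" in df.columns else None
    marker_cols = [c for c in df.columns if c not in RESERVED_PHENO_COLS]
    biomarkers = df[marker_cols].apply(pd.to_numeric).copy()
    biomarkers.index = pd.Index(sample_ids, name="sample_id")
    return PhenotypeTable(sample_ids, status, cal, biomarkers)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": pheno.sample_ids, "status": pheno.status})
    df["cal"] = pheno.cal
    for name in pheno.biomarker_names:
        df[name] = pheno.biomarkers[name].to_numpy()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
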