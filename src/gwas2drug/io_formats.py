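"""Typed readers and writers for every external table the pipeline touches.

All coordinates are 1-based inclusive (GWAS/GTF convention). Missing values
are encoded as ``NA``; empty strings are treated identically. Readers drop
malformed rows, log the counts, and raise on structural problems (missing
columns, inconsistent LD blocks) rather than guessing.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PSD_TOL = 1e-8

GWAS_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "beta", "se", "p", "n"]
GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand"]


class FormatError(ValueError):
    """A file violates its documented schema."""


class ConsistencyError(ValueError):
    """Tables are individually valid but mutually inconsistent."""


@dataclass(frozen=True)
class SnpStat:
    """One SNP's summary association plus genomic location.

    ``z`` is derived as beta/se; ``p`` lives in the half-open-below interval
    (0, 1] (a p of exactly 1 is legal).
    """

    snp_id: str
    chrom: str
    pos: int
    a1: str
    a2: str
    beta: float
    se: float
    p: float
    n: int
    z: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", self.beta / self.se)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body: 1-based inclusive span and strand."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"{self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: strand must be + or -")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class LDReference:
    """Blockwise SNP correlation matrices; each SNP in exactly one block."""

    blocks: list[tuple[list[str], np.ndarray]]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ids, mat in self.blocks:
            validate_correlation_block(ids, mat)
            dup = seen.intersection(ids)
            if dup:
                raise ConsistencyError(
                    f"SNPs repeated across LD blocks: {sorted(dup)[:5]}"
                )
            seen.update(ids)

    def snp_index(self) -> dict[str, tuple[int, int]]:
        """Map snp_id -> (block index, position within block)."""
        out: dict[str, tuple[int, int]] = {}
        for b, (ids, _) in enumerate(self.blocks):
            for j, s in enumerate(ids):
                out[s] = (b, j)
        return out


def validate_correlation_block(ids: Sequence[str], mat: np.ndarray) -> None:
    k = len(ids)
    if mat.shape != (k, k):
        raise FormatError(f"LD block not square: {mat.shape} for {k} SNPs")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-6):
        raise FormatError("LD block diagonal is not 1")
    if np.abs(mat).max() > 1.0 + 1e-9:
        raise FormatError("LD block has |r| > 1")
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise FormatError("LD block not symmetric after symmetrization")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -PSD_TOL:
        raise FormatError(f"LD block not PSD (min eigenvalue {w.min():.3g})")


@dataclass(frozen=True)
class DruggabilityTier:
    """Druggable-genome tier label; unlisted genes are 'none'."""

    gene_id: str
    tier: str

    VALID = ("T1", "T2", "T3", "none")

    def __post_init__(self) -> None:
        if self.tier not in self.VALID:
            raise FormatError(f"{self.gene_id}: unknown tier {self.tier!r}")


def _clean(df: pd.DataFrame) -> pd.DataFrame:
    return df.replace("", np.nan).replace("NA", np.nan)


def read_gwas(path: str | Path, min_maf: float | None = None) -> list[SnpStat]:
    """Read a GWAS summary-statistic TSV into validated :class:`SnpStat` rows.

    Rows with missing or invalid fields (se <= 0, p outside (0, 1], non-finite
    beta) are dropped and counted in the log. ``min_maf`` filters on an
    optional ``maf`` column when present.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp": str})
    missing = [c for c in GWAS_COLUMNS if c not in df.columns and c != "n"]
    if missing:
        raise FormatError(f"GWAS file missing mandatory column(s): {missing}")
    if "n" not in df.columns:
        df["n"] = 0
    df = _clean(df)
    n_in = len(df)
    for col in ("pos", "beta", "se", "p", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (
        df[["snp", "chrom", "pos", "a1", "a2", "beta", "se", "p"]].notna().all(axis=1)
        & (df["se"] > 0)
        & (df["p"] > 0)
        & (df["p"] <= 1.0)
        & np.isfinite(df["beta"])
    )
    if min_maf is not None and "maf" in df.columns:
        ok &= pd.to_numeric(df["maf"], errors="coerce") >= min_maf
    dropped = int(n_in - ok.sum())
    if dropped:
        log.warning("read_gwas: dropped %d of %d rows failing validation", dropped, n_in)
    df = df[ok]
    key = df[["chrom", "pos", "a1", "a2"]].astype(str).agg(":".join, axis=1)
    if key.duplicated().any():
        raise ConsistencyError("duplicate (chrom,pos,a1,a2) rows in GWAS file")
    return [
        SnpStat(
            snp_id=str(r.snp), chrom=str(r.chrom), pos=int(r.pos),
            a1=str(r.a1), a2=str(r.a2), beta=float(r.beta), se=float(r.se),
            p=float(r.p), n=int(r.n),
        )
        for r in df.itertuples()
    ]


def write_gwas(snps: Iterable[SnpStat], path: str | Path) -> None:
    rows = [
        dict(snp=s.snp_id, chrom=s.chrom, pos=s.pos, a1=s.a1, a2=s.a2,
             beta=s.beta, se=s.se, p=s.p, n=s.n)
        for s in snps
    ]
    df = pd.DataFrame(rows, columns=GWAS_COLUMNS)
    _write_tsv(df, path, sci_cols={"p"})


def read_genes(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gene annotation missing column(s): {missing}")
    df = _clean(df).dropna(subset=GENE_COLUMNS)
    return [
        GeneAnnotation(
            gene_id=r.gene_id, symbol=r.symbol, chrom=str(r.chrom),
            start=int(r.start), end=int(r.end), strand=r.strand,
        )
        for r in df.itertuples()
    ]


def write_genes(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(g) for g in genes], columns=GENE_COLUMNS)
    _write_tsv(df, path)


# LD block file grammar (plain text, documented in README):
#   # comment lines anywhere
#   BLOCK <block_id> <k>
#   SNPS <id_1> ... <id_k>
#   <k lines of k whitespace-separated correlations, row-major>
def read_ld(path: str | Path) -> LDReference:
    """Parse a blockwise LD file; symmetry is enforced by averaging M and Mᵀ."""
    blocks: list[tuple[list[str], np.ndarray]] = []
    lines = [
        ln.strip() for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    i = 0
    while i < len(lines):
        head = lines[i].split()
        if head[0] != "BLOCK" or len(head) != 3:
            raise FormatError(f"expected 'BLOCK <id> <k>', got: {lines[i]!r}")
        k = int(head[2])
        snp_line = lines[i + 1].split()
        if snp_line[0] != "SNPS" or len(snp_line) != k + 1:
            raise FormatError(f"block {head[1]}: SNPS line does not list {k} ids")
        ids = snp_line[1:]
        rows = []
        for j in range(k):
            vals = [float(v) for v in lines[i + 2 + j].split()]
            if len(vals) != k:
                raise FormatError(f"block {head[1]}: row {j} has {len(vals)} != {k} entries")
            rows.append(vals)
        mat = np.asarray(rows, dtype=float)
        mat = 0.5 * (mat + mat.T)
        blocks.append((ids, mat))
        i += 2 + k
    return LDReference(blocks=blocks, provenance=str(path))


def write_ld(ld: LDReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# LD block file: BLOCK <id> <k> / SNPS <ids...> / k rows of k correlations\n")
        for b, (ids, mat) in enumerate(ld.blocks):
            fh.write(f"BLOCK {b} {len(ids)}\n")
            fh.write("SNPS " + " ".join(ids) + "\n")
            for row in mat:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_tiers(path: str | Path) -> dict[str, str]:
    """gene_id -> tier; duplicate genes with conflicting tiers are an error."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "tier"):
        if col not in df.columns:
            raise FormatError(f"tier table missing column {col}")
    df = _clean(df).dropna()
    out: dict[str, str] = {}
    for r in df.itertuples():
        DruggabilityTier(r.gene_id, r.tier)  # validates label
        if r.gene_id in out and out[r.gene_id] != r.tier:
            raise ConsistencyError(f"gene {r.gene_id} has conflicting tiers")
        out[r.gene_id] = r.tier
    return out


def write_tiers(tiers: dict[str, str], path: str | Path) -> None:
    df = pd.DataFrame(sorted(tiers.items()), columns=["gene_id", "tier"])
    _write_tsv(df, path)


def _write_tsv(df: pd.DataFrame, path: str | Path, sci_cols: set[str] | None = None) -> None:
    """TSV with stable column order, floats at 6 significant digits,
    p-value-like columns in scientific notation."""
    sci_cols = sci_cols or {c for c in df.columns if c == "p" or c.startswith("p_") or c.endswith("_p") or c in ("q_value",)}
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            fmt = "{:.6e}" if col in sci_cols else "{:.6g}"
            out[col] = out[col].map(lambda v, f=fmt: "NA" if not math.isfinite(v) else f.format(v))
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_results_table(records: Sequence, path: str | Path) -> None:
    """Serialize a homogeneous list of result dataclasses as TSV.

    An empty list is legal only when the caller has nothing to report; it
    yields an empty file with no header (the record type is unknown).
    """
    if not records:
        Path(path).write_text("")
        return
    cls = type(records[0])
    if any(type(r) is not cls for r in records):
        raise TypeError("write_results_table requires records of one type")
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        # flatten nested containers deterministically
        for k, v in list(d.items()):
            if isinstance(v, dict):
                d[k] = ";".join(f"{kk}={vv}" for kk, vv in sorted(v.items()))
            elif isinstance(v, (list, tuple, set, frozenset)):
                d[k] = ";".join(str(x) for x in sorted(v))
        rows.append(d)
    df = pd.DataFrame(rows)
    _write_tsv(df, path)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV as a DataFrame (NA-aware)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
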