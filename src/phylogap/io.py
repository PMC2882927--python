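"""Readers and writers for the external formats the pipeline touches.

Microsatellite genotypes travel as STRUCTURE two-rows-per-individual text or
Genepop 3-digit text; mtDNA alignments as FASTA; sample localities as CSV;
climate and suitability layers as ESRI ASCII grids.  Every reader validates
its input and every reader/writer pair round-trips bit-faithfully.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: sentinel for a missing allele inside GenotypeMatrix.alleles
MISSING = -9


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid multi-locus microsatellite genotypes with locality labels.

    ``alleles`` has shape (n_individuals, n_loci, 2) and holds integer
    allele sizes (repeat counts); missing entries carry :data:`MISSING`,
    never a silent zero.
    """

    individual_ids: list[str]
    locality_ids: list[str]
    loci: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n, L = len(self.individual_ids), len(self.loci)
        if len(self.locality_ids) != n:
            raise ValueError("locality_ids must parallel individual_ids")
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n}, {L}, 2)")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L, 2) mask of missing allele entries."""
        return self.alleles == MISSING

    def localities(self) -> list[str]:
        """Unique locality ids in order of first appearance."""
        seen: dict[str, None] = {}
        for loc in self.locality_ids:
            seen.setdefault(loc)
        return list(seen)

    def subset(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in keep],
            [self.locality_ids[i] for i in keep],
            list(self.loci),
            self.alleles[keep].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.locality_ids == other.locality_ids
            and self.loci == other.loci
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass
class SequenceAlignment:
    """Aligned haploid DNA sequences with optional per-sequence metadata."""

    ids: list[str]
    sequences: list[str]
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment must contain at least one sequence")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]
        bad = set("".join(self.sequences)) - set("ACGTN-")
        if bad:
            raise ValueError(f"unexpected characters in alignment: {bad}")
        if (length := len(self.sequences[0])) == 0:
            raise ValueError("alignment length must be positive")
        self.length = length

    @property
    def n(self) -> int:
        return len(self.ids)

    def array(self) -> np.ndarray:
        """(n, length) array of single-character bytes."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype="S1"
        ).reshape(self.n, self.length)


@dataclass
class LocalityTable:
    """Sample localities: id, decimal-degree coordinates, optional cluster."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"locality_id", "latitude", "longitude"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"locality table needs columns {sorted(required)}")
        if self.frame["locality_id"].duplicated().any():
            raise ValueError("locality_id values must be unique")
        lat = self.frame["latitude"].astype(float)
        lon = self.frame["longitude"].astype(float)
        if (lat.abs() > 90).any() or (lon.abs() > 180).any():
            raise ValueError("coordinates out of range")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return self.frame["locality_id"].astype(str).tolist()

    def coords(self) -> np.ndarray:
        """(n, 2) array of (latitude, longitude)."""
        return self.frame[["latitude", "longitude"]].to_numpy(dtype=float)

    def cluster_of(self) -> dict[str, str]:
        if "cluster_label" not in self.frame.columns:
            return {}
        return dict(zip(self.ids, self.frame["cluster_label"].astype(str)))


@dataclass
class Raster:
    """ESRI-ASCII-style georeferenced grid.

    ``values`` is row-major with row 0 the top (northernmost) row;
    ``xllcorner``/``yllcorner`` locate the lower-left corner of the
    lower-left cell, following the ESRI convention.
    """

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.nrows, self.ncols):
            raise ValueError(
                f"values shape {self.values.shape} != ({self.nrows}, {self.ncols})")

    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata_value

    def data_values(self) -> np.ndarray:
        """1-D array of valid (non-nodata) cell values."""
        return self.values[~self.nodata_mask()]

    def like(self, values: np.ndarray) -> "Raster":
        """New raster sharing this header with the given values."""
        return Raster(self.ncols, self.nrows, self.xllcorner, self.yllcorner,
                      self.cellsize, self.nodata_value, values)

    def same_header(self, other: "Raster") -> bool:
        return (
            self.ncols == other.ncols and self.nrows == other.nrows
            and self.xllcorner == other.xllcorner
            and self.yllcorner == other.yllcorner
            and self.cellsize == other.cellsize
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Raster):
            return NotImplemented
        return self.same_header(other) and np.array_equal(
            self.values, other.values) and self.nodata_value == other.nodata_value


class ClimateStack(dict):
    """Named climate layers sharing one grid header."""

    def __init__(self, layers: Mapping[str, Raster]):
        super().__init__(layers)
        rasters = list(self.values())
        if not rasters:
            raise ValueError("empty climate stack")
        ref = rasters[0]
        for r in rasters[1:]:
            if not ref.same_header(r):
                raise ValueError("climate layers must share one grid header")
        self.ref = ref

    def variable_names(self) -> list[str]:
        return list(self.keys())


# ---------------------------------------------------------------------------
# Microsatellite genotype text
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, dialect: str = "structure_2row") -> GenotypeMatrix:
    """Read a genotype file in the named dialect.

    ``structure_2row``: one header line of locus names, then two lines per
    individual (``id locality a1 a2 ... aL`` with -9 for missing).
    ``genepop``: title line, locus names (one per line or comma-separated),
    ``Pop`` blocks, ``id , 3-digit diploid codes`` with 000 = missing.
    """
    if dialect == "structure_2row":
        return _read_structure(Path(path))
    if dialect == "genepop":
        return _read_genepop(Path(path))
    raise ValueError(f"unknown genotype dialect: {dialect!r}")


def _read_structure(path: Path) -> GenotypeMatrix:
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    loci = lines[0].split()
    body = lines[1:]
    if len(body) % 2:
        raise ParseError(f"{path}: odd number of genotype rows")
    ids, locs, rows = [], [], []
    for pair_start in range(0, len(body), 2):
        two = []
        for off in (0, 1):
            lineno = pair_start + off + 2
            parts = body[pair_start + off].split()
            if len(parts) != 2 + len(loci):
                raise ParseError(
                    f"{path}:{lineno}: expected {2 + len(loci)} fields, got {len(parts)}")
            try:
                alleles = [int(tok) for tok in parts[2:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad allele token ({exc})") from None
            two.append((parts[0], parts[1], alleles))
        if two[0][:2] != two[1][:2]:
            raise ParseError(
                f"{path}:{pair_start + 2}: row pair ids/localities disagree")
        ids.append(two[0][0])
        locs.append(two[0][1])
        rows.append(np.stack([two[0][2], two[1][2]], axis=1))
    alleles = np.stack(rows)  # (n, L, 2)
    alleles[alleles < 0] = MISSING
    return GenotypeMatrix(ids, locs, loci, alleles)


def write_genotypes(gm: GenotypeMatrix, path: str | Path,
                    dialect: str = "structure_2row") -> None:
    path = Path(path)
    if dialect == "structure_2row":
        out = [" ".join(gm.loci)]
        for i, (ind, loc) in enumerate(zip(gm.individual_ids, gm.locality_ids)):
            for copy in (0, 1):
                row = [str(int(a)) for a in gm.alleles[i, :, copy]]
                out.append(" ".join([ind, loc] + row))
        path.write_text("\n".join(out) + "\n")
    elif dialect == "genepop":
        out = ["phylogap genotypes"]
        out.extend(gm.loci)
        current = None
        for i, loc in enumerate(gm.locality_ids):
            if loc != current:
                out.append("Pop")
                current = loc
            codes = []
            for l in range(gm.n_loci):
                a, b = gm.alleles[i, l]
                a = 0 if a == MISSING else int(a)
                b = 0 if b == MISSING else int(b)
                codes.append(f"{a:03d}{b:03d}")
            out.append(f"{gm.locality_ids[i]}_{gm.individual_ids[i]} , " + " ".join(codes))
        path.write_text("\n".join(out) + "\n")
    else:
        raise ValueError(f"unknown genotype dialect: {dialect!r}")


def _read_genepop(path: Path) -> GenotypeMatrix:
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated genepop file")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend(tok.strip() for tok in lines[i].split(",") if tok.strip())
        i += 1
    if not loci:
        raise ParseError(f"{path}: no locus names before first Pop")
    ids, locs, rows = [], [], []
    pop_idx = 0
    for lineno, line in enumerate(lines[i:], start=i + 1):
        if line.strip().lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise ParseError(f"{path}:{lineno}: genotype line lacks comma")
        name, geno = line.split(",", 1)
        toks = geno.split()
        if len(toks) != len(loci):
            raise ParseError(
                f"{path}:{lineno}: expected {len(loci)} genotypes, got {len(toks)}")
        pair = []
        for tok in toks:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ParseError(f"{path}:{lineno}: bad genotype token {tok!r}")
            w = len(tok) // 2
            a, b = int(tok[:w]), int(tok[w:])
            pair.append((a if a else MISSING, b if b else MISSING))
        # locality is encoded as the prefix before the last underscore when
        # written by write_genotypes; otherwise fall back to the Pop index
        name = name.strip()
        loc, _, ind = name.rpartition("_")
        if not loc:
            loc, ind = f"pop{pop_idx}", name
        ids.append(ind)
        locs.append(loc)
        rows.append(np.array(pair))
    if not ids:
        raise ParseError(f"{path}: no genotype lines")
    return GenotypeMatrix(ids, locs, loci, np.stack(rows))


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> SequenceAlignment:
    """Read an aligned FASTA file, preserving order and uppercasing bases."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return SequenceAlignment(
        [r.id for r in records], [str(r.seq).upper() for r in records])


def write_fasta(aln: SequenceAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(aln.ids, aln.sequences):
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Locality CSV
# ---------------------------------------------------------------------------

def read_localities(path: str | Path) -> LocalityTable:
    return LocalityTable(pd.read_csv(path, dtype={"locality_id": str}))


def write_localities(table: LocalityTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)


# ---------------------------------------------------------------------------
# ESRI ASCII grids
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (.asc): 6-line header then row-major values."""
    path = Path(path)
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            line = fh.readline()
            if not line:
                raise ParseError(f"{path}: truncated header")
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key not in _HEADER_KEYS:
                raise ParseError(f"{path}: unexpected header key {key!r}")
            header[key] = float(val)
        missing = set(_HEADER_KEYS) - set(header)
        if missing:
            raise ParseError(f"{path}: missing header keys {sorted(missing)}")
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    if values.size != nrows * ncols:
        raise ParseError(
            f"{path}: expected {nrows * ncols} values, got {values.size}")
    return Raster(ncols, nrows, header["xllcorner"], header["yllcorner"],
                  header["cellsize"], header["nodata_value"],
                  values.reshape(nrows, ncols))


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid with full float precision (repr round-trip)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {float(raster.xllcorner)!r}\n")
        fh.write(f"yllcorner {float(raster.yllcorner)!r}\n")
        fh.write(f"cellsize {float(raster.cellsize)!r}\n")
        fh.write(f"NODATA_value {float(raster.nodata_value)!r}\n")
        for row in raster.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_climate_stack(paths: Mapping[str, str | Path]) -> ClimateStack:
    """Load named .asc layers, enforcing one shared header."""
    return ClimateStack({name: read_ascii_grid(p) for name, p in paths.items()})
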