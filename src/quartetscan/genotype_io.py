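"""Genotype, population-map and scaffold-map I/O.

Reads multi-sample VCFs into a compact dosage matrix, parses the
sample→taxon quartet assignment and the scaffold→chromosome placement
map, lifts scaffold coordinates onto chromosomes, and tiles fixed-size
windows over the result.

All coordinates are 0-based half-open internally; VCF's 1-based
positions are converted on read and write.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

MISSING = -1  # sentinel for missing dosage / depth


class FormatError(ValueError):
    """Malformed input file (duplicate samples, bad columns, ...)."""


class ConfigError(ValueError):
    """Inconsistent or incomplete configuration."""


class MapError(ValueError):
    """Invalid scaffold→chromosome placement (e.g. overlapping scaffolds)."""


class InsufficientDataError(ValueError):
    """Not enough data for the requested resampling scheme."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Per-site, per-sample allele dosages over scaffold/chromosome coordinates.

    Parameters
    ----------
    chroms : array of str
        Scaffold or chromosome id per site.
    pos : array of int
        0-based position per site, strictly increasing within a sequence.
    ref, alt : arrays of str
        Reference and single alternate allele per site.
    dosages : int array, shape (n_sites, n_samples)
        Count of alternate alleles in {0, 1, 2}; ``MISSING`` (-1) for no call.
    samples : list of str
    depths : int array or None
        Per-genotype read depth (DP); ``MISSING`` where absent.
    unplaced : bool array or None
        Set by :func:`lift_to_chromosome` for sites on scaffolds absent
        from the placement map.
    """

    chroms: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray
    samples: list[str]
    depths: np.ndarray | None = None
    unplaced: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        if self.dosages.shape != (self.n_sites, self.n_samples):
            raise FormatError("dosage matrix shape does not match sites x samples")
        d = self.dosages
        if d.size and not np.all((d >= -1) & (d <= 2)):
            raise FormatError("dosages must lie in {0,1,2} or be missing")
        for c in np.unique(self.chroms):
            p = self.pos[self.chroms == c]
            if np.any(np.diff(p) <= 0):
                raise FormatError(f"positions not strictly increasing on {c}")

    def take(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Subset sites by integer or boolean index."""
        return GenotypeMatrix(
            chroms=self.chroms[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosages=self.dosages[idx],
            samples=list(self.samples),
            depths=None if self.depths is None else self.depths[idx],
            unplaced=None if self.unplaced is None else self.unplaced[idx],
        )

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Integer indices of sites in [start, end) on ``chrom``."""
        on = np.flatnonzero(self.chroms == chrom)
        p = self.pos[on]
        lo = np.searchsorted(p, start, side="left")
        hi = np.searchsorted(p, end, side="left")
        return on[lo:hi]


@dataclass(frozen=True)
class QuartetSpec:
    """Ordered (P1, P2, P3, O) assignment of samples to the four taxa."""

    p1: tuple[str, ...]
    p2: tuple[str, ...]
    p3: tuple[str, ...]
    o: tuple[str, ...]
    labels: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        groups = [self.p1, self.p2, self.p3, self.o]
        if any(len(g) == 0 for g in groups):
            raise ConfigError("every quartet role needs at least one sample")
        flat = [s for g in groups for s in g]
        if len(set(flat)) != len(flat):
            raise FormatError("a sample is assigned to more than one quartet role")

    @property
    def roles(self) -> dict:
        return {"P1": self.p1, "P2": self.p2, "P3": self.p3, "O": self.o}

    def indices(self, samples: Sequence[str]) -> dict:
        """Column indices of each role in a sample list."""
        lookup = {s: i for i, s in enumerate(samples)}
        missing = [s for g in self.roles.values() for s in g if s not in lookup]
        if missing:
            raise ConfigError(f"quartet samples absent from matrix: {missing}")
        return {r: np.array([lookup[s] for s in g], dtype=int)
                for r, g in self.roles.items()}

    def swapped(self) -> "QuartetSpec":
        """Quartet with P1 and P2 exchanged (D changes sign)."""
        return QuartetSpec(self.p2, self.p1, self.p3, self.o, dict(self.labels))


@dataclass(frozen=True)
class ScaffoldPlacement:
    chrom: str
    offset: int
    strand: str = "+"
    length: int | None = None


@dataclass(frozen=True)
class Window:
    """0-based half-open interval on a chromosome (or unplaced scaffold)."""

    chrom: str
    start: int
    end: int
    size: int  # nominal size class
    partial: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_TO_DOSAGE = {0: 0, 1: 1, 2: MISSING, 3: 2}  # cyvcf2 gt_types codes


def read_vcf_genotypes(path: str, min_qual: float = 30.0) -> GenotypeMatrix:
    """Read biallelic SNPs with QUAL strictly above ``min_qual`` from a VCF.

    Multiallelic records and indels are dropped, not split. Dosage is the
    count of alternate alleles; missing genotypes are recorded as
    ``MISSING``. Per-genotype DP is copied when the FORMAT field exists.
    """
    from cyvcf2 import VCF

    if min_qual < 0:
        raise ConfigError("min_qual must be >= 0")
    try:
        vcf = VCF(str(path), gts012=False)
    except OSError as exc:
        raise IOError(f"cannot read VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise FormatError("duplicate sample ids in VCF header")

    has_dp = "DP" in {f for f in _format_ids(vcf)}
    chroms, pos, ref, alt, dosages, depths = [], [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue  # indel / MNP
        if v.ALT[0] not in "ACGT" or v.REF not in "ACGT":
            continue
        if v.QUAL is None or not (v.QUAL > min_qual):
            continue
        chroms.append(v.CHROM)
        pos.append(v.start)  # 0-based
        ref.append(v.REF)
        alt.append(v.ALT[0])
        dosages.append([_GT_TO_DOSAGE[t] for t in v.gt_types])
        if has_dp:
            dp = v.format("DP")
            if dp is None:
                depths.append(np.full(len(samples), MISSING, dtype=np.int32))
            else:
                dp = dp.reshape(-1).astype(np.int64)
                depths.append(np.where((dp < 0) | (dp > 2**30), MISSING, dp))
    vcf.close()

    n = len(pos)
    mat = GenotypeMatrix(
        chroms=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosages=(np.array(dosages, dtype=np.int8)
                 if n else np.empty((0, len(samples)), dtype=np.int8)),
        samples=samples,
        depths=(np.array(depths, dtype=np.int32) if (has_dp and n) else None),
    )
    mat.validate()
    return mat


def _format_ids(vcf) -> Iterator[str]:
    for h in vcf.header_iter():
        try:
            if h["HeaderType"] == "FORMAT":
                yield h["ID"]
        except KeyError:
            continue


def write_vcf(matrix: GenotypeMatrix, path: str, qual: float = 60.0) -> None:
    """Write the matrix as minimal VCF 4.2 text (GT, and DP when present)."""
    has_dp = matrix.depths is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=quartetscan\n")
        seen = []
        for c in matrix.chroms:
            if c not in seen:
                seen.append(c)
        for c in seen:
            end = int(matrix.pos[matrix.chroms == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={end}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        fmt = "GT:DP" if has_dp else "GT"
        for i in range(matrix.n_sites):
            fields = [
                str(matrix.chroms[i]), str(int(matrix.pos[i]) + 1), ".",
                str(matrix.ref[i]), str(matrix.alt[i]),
                f"{qual:g}", "PASS", ".", fmt,
            ]
            for j in range(matrix.n_samples):
                cell = gt_strings[int(matrix.dosages[i, j])]
                if has_dp:
                    dp = int(matrix.depths[i, j])
                    cell += ":" + ("." if dp == MISSING else str(dp))
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Population and scaffold maps
# ---------------------------------------------------------------------------

_ROLES = {"P1", "P2", "P3", "O"}


def read_population_map(path: str) -> QuartetSpec:
    """Parse a TSV of (sample, taxon, role); role ∈ {P1,P2,P3,O,ignore}."""
    assigned: dict[str, str] = {}
    taxa: dict[str, list[str]] = {r: [] for r in _ROLES}
    members: dict[str, list[str]] = {r: [] for r in _ROLES}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected sample<TAB>taxon<TAB>role")
            sample, taxon, role = parts[0], parts[1], parts[2].strip()
            if role.lower() == "ignore":
                continue
            if role not in _ROLES:
                raise FormatError(f"{path}:{ln}: unknown role {role!r}")
            if sample in assigned:
                raise FormatError(
                    f"sample {sample!r} assigned to both {assigned[sample]} and {role}")
            assigned[sample] = role
            members[role].append(sample)
            if taxon not in taxa[role]:
                taxa[role].append(taxon)
    empty = [r for r in ("P1", "P2", "P3", "O") if not members[r]]
    if empty:
        raise ConfigError(f"population map missing samples for roles: {empty}")
    labels = {r: "+".join(taxa[r]) for r in _ROLES}
    return QuartetSpec(tuple(members["P1"]), tuple(members["P2"]),
                       tuple(members["P3"]), tuple(members["O"]), labels)


def read_scaffold_map(path: str) -> dict[str, ScaffoldPlacement]:
    """Parse a TSV of scaffold placements.

    Columns: scaffold, chromosome, offset, strand, [length]. Length is
    required for reverse-oriented scaffolds (coordinate flipping needs it).
    """
    out: dict[str, ScaffoldPlacement] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(
                    f"{path}:{ln}: expected scaffold<TAB>chrom<TAB>offset<TAB>strand[<TAB>length]")
            scaf, chrom, offset, strand = parts[:4]
            if scaf in out:
                raise FormatError(f"{path}:{ln}: duplicate scaffold {scaf!r}")
            length = int(parts[4]) if len(parts) > 4 and parts[4] else None
            off = int(offset)
            if off < 0:
                raise MapError(f"{path}:{ln}: negative offset")
            if strand not in "+-":
                raise FormatError(f"{path}:{ln}: strand must be + or -")
            out[scaf] = ScaffoldPlacement(chrom, off, strand, length)
    _check_overlaps(out)
    return out


def _check_overlaps(smap: dict[str, ScaffoldPlacement]) -> None:
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for scaf, pl in smap.items():
        if pl.length is None:
            continue
        by_chrom.setdefault(pl.chrom, []).append((pl.offset, pl.offset + pl.length, scaf))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s0, e0, a), (s1, _e1, b) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise MapError(f"scaffolds {a!r} and {b!r} overlap on {chrom}")


# ---------------------------------------------------------------------------
# Coordinate lifting and windowing
# ---------------------------------------------------------------------------

def lift_to_chromosome(matrix: GenotypeMatrix,
                       scaffold_map: dict[str, ScaffoldPlacement]) -> GenotypeMatrix:
    """Re-express scaffold coordinates as chromosome coordinates.

    Forward scaffolds map ``pos → offset + pos``; reverse-oriented
    scaffolds are flipped (``pos → offset + length − 1 − pos``). Scaffolds
    absent from the map are retained under their own name and flagged
    unplaced. Sites are re-sorted within each chromosome.
    """
    _check_overlaps(scaffold_map)
    n = matrix.n_sites
    new_chrom = np.empty(n, dtype=object)
    new_pos = np.empty(n, dtype=np.int64)
    unplaced = np.zeros(n, dtype=bool)
    for i in range(n):
        scaf = matrix.chroms[i]
        pl = scaffold_map.get(scaf)
        if pl is None:
            new_chrom[i] = scaf
            new_pos[i] = matrix.pos[i]
            unplaced[i] = True
            continue
        new_chrom[i] = pl.chrom
        if pl.strand == "+":
            new_pos[i] = pl.offset + matrix.pos[i]
        else:
            if pl.length is None:
                raise MapError(f"reverse-oriented scaffold {scaf!r} needs a length")
            new_pos[i] = pl.offset + pl.length - 1 - matrix.pos[i]
    order = np.lexsort((new_pos, new_chrom.astype(str)))
    lifted = GenotypeMatrix(
        chroms=new_chrom[order], pos=new_pos[order],
        ref=matrix.ref[order], alt=matrix.alt[order],
        dosages=matrix.dosages[order], samples=list(matrix.samples),
        depths=None if matrix.depths is None else matrix.depths[order],
        unplaced=unplaced[order],
    )
    lifted.validate()
    return lifted


def lift_from_chromosome(matrix: GenotypeMatrix,
                         scaffold_map: dict[str, ScaffoldPlacement]) -> GenotypeMatrix:
    """Invert :func:`lift_to_chromosome` (placements need lengths)."""
    ivs: dict[str, list[tuple[int, int, str]]] = {}
    for scaf, pl in scaffold_map.items():
        if pl.length is None:
            raise MapError(f"scaffold {scaf!r} needs a length to invert the lift")
        ivs.setdefault(pl.chrom, []).append((pl.offset, pl.offset + pl.length, scaf))
    for v in ivs.values():
        v.sort()
    n = matrix.n_sites
    new_chrom = np.empty(n, dtype=object)
    new_pos = np.empty(n, dtype=np.int64)
    for i in range(n):
        chrom, p = matrix.chroms[i], int(matrix.pos[i])
        if matrix.unplaced is not None and matrix.unplaced[i]:
            new_chrom[i], new_pos[i] = chrom, p
            continue
        hit = None
        for s, e, scaf in ivs.get(chrom, ()):
            if s <= p < e:
                hit = (s, e, scaf)
                break
        if hit is None:
            raise MapError(f"no scaffold covers {chrom}:{p}")
        s, e, scaf = hit
        pl = scaffold_map[scaf]
        new_chrom[i] = scaf
        new_pos[i] = p - s if pl.strand == "+" else pl.length - 1 - (p - s)
    order = np.lexsort((new_pos, new_chrom.astype(str)))
    out = replace(matrix, chroms=new_chrom[order], pos=new_pos[order],
                  ref=matrix.ref[order], alt=matrix.alt[order],
                  dosages=matrix.dosages[order],
                  depths=None if matrix.depths is None else matrix.depths[order],
                  unplaced=None)
    out.validate()
    return out


def iter_windows(matrix: GenotypeMatrix, size: int,
                 lengths: dict[str, int] | None = None,
                 include_unplaced: bool = False) -> Iterator[Window]:
    """Tile non-overlapping windows of ``size`` bp from coordinate 0.

    The terminal partial window is emitted with its true length and
    flagged partial. Chromosome lengths default to (max site position + 1).
    Unplaced scaffolds are skipped unless ``include_unplaced``.
    """
    if size <= 0:
        raise ConfigError("window size must be positive")
    seen: list[str] = []
    for c in matrix.chroms:
        if c not in seen:
            seen.append(c)
    for chrom in seen:
        on = matrix.chroms == chrom
        if (not include_unplaced and matrix.unplaced is not None
                and matrix.unplaced[on].any()):
            continue
        length = (lengths or {}).get(chrom)
        if length is None:
            length = int(matrix.pos[on].max()) + 1
        start = 0
        while start < length:
            end = min(start + size, length)
            yield Window(chrom, start, end, size, partial=(end - start < size))
            start += size
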