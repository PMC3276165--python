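"""Readers and writers for the classic imputation text-file dialects.

The on-disk formats are the space-separated files used throughout the
genotype-imputation literature:

* ``.legend`` — one header line (``id position a0 a1``) then one line per
  biallelic SNP;
* ``.hap`` — one line per SNP, one 0/1 token per haplotype;
* ``.gen`` — one line per SNP: ``id rsid position a0 a1`` followed by a
  genotype-probability triple per individual;
* ``.sample`` — individual identifiers, two header lines then one per sample;
* genetic map — three columns (position, rate in cM/Mb, cumulative cM) with a
  header line.

All positions are 1-based base-pair coordinates, as in the source formats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FormatError",
    "VariantSite",
    "HaplotypePanel",
    "GenotypeMatrix",
    "GeneticMap",
    "MISSING",
    "read_hap_legend",
    "write_hap_legend",
    "read_gen",
    "write_gen",
    "read_sample",
    "write_sample",
    "read_genetic_map",
    "write_genetic_map",
    "match_sites",
]

#: Sentinel for a missing genotype in :class:`GenotypeMatrix`.
MISSING: int = -1


class FormatError(ValueError):
    """A file violated the expected grammar; the message names the line."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP: identifier, 1-based position and its two alleles."""

    id: str
    position: int
    allele0: str
    allele1: str

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"position must be positive, got {self.position}")
        if self.allele0 == self.allele1:
            raise ValueError(f"alleles must differ at site {self.id}")


def _check_sorted(sites: Sequence[VariantSite]) -> None:
    pos = np.array([s.position for s in sites])
    if len(pos) > 1 and not np.all(np.diff(pos) > 0):
        raise ValueError("sites must be strictly increasing in position")


@dataclass
class HaplotypePanel:
    """Phased haplotypes: a (sites x haplotypes) matrix of 0/1 alleles."""

    sites: list[VariantSite]
    alleles: np.ndarray  # (n_sites, n_haplotypes), uint8 in {0,1}
    haplotype_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[0] != len(self.sites):
            raise ValueError(
                f"{len(self.sites)} sites but {self.alleles.shape[0]} allele rows"
            )
        if not self.haplotype_ids:
            self.haplotype_ids = [f"hap{i}" for i in range(self.alleles.shape[1])]
        if len(self.haplotype_ids) != self.alleles.shape[1]:
            raise ValueError("haplotype_ids length does not match allele columns")
        if self.alleles.size and self.alleles.max(initial=0) > 1:
            raise ValueError("allele entries must be 0 or 1")
        _check_sorted(self.sites)

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=np.int64)

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of allele 1 at each site."""
        return self.alleles.mean(axis=1)

    def minor_allele_frequencies(self) -> np.ndarray:
        f = self.allele_frequencies()
        return np.minimum(f, 1.0 - f)

    def subset_sites(self, index: np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HaplotypePanel(
            sites=[self.sites[i] for i in index],
            alleles=self.alleles[index],
            haplotype_ids=list(self.haplotype_ids),
        )

    def subset_haplotypes(self, index: np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HaplotypePanel(
            sites=list(self.sites),
            alleles=self.alleles[:, index],
            haplotype_ids=[self.haplotype_ids[i] for i in index],
        )


@dataclass
class GenotypeMatrix:
    """Unphased study genotypes in {0,1,2,MISSING}, (sites x individuals)."""

    sites: list[VariantSite]
    genotypes: np.ndarray  # int8, entries in {0,1,2,MISSING}
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if self.genotypes.shape[0] != len(self.sites):
            raise ValueError(
                f"{len(self.sites)} sites but {self.genotypes.shape[0]} genotype rows"
            )
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(self.genotypes.shape[1])]
        if len(self.individual_ids) != self.genotypes.shape[1]:
            raise ValueError("individual_ids length does not match genotype columns")
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.genotypes[~valid].flat[0]
            raise ValueError(f"genotype entries must be in {{0,1,2,missing}}, got {bad}")
        _check_sorted(self.sites)

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=np.int64)

    def subset_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sites=[self.sites[i] for i in index],
            genotypes=self.genotypes[index],
            individual_ids=list(self.individual_ids),
        )


@dataclass
class GeneticMap:
    """Cumulative genetic map: base-pair positions -> centimorgans.

    Interpolation is linear in position; queries beyond either end use
    constant extrapolation (the boundary cM value).
    """

    positions: np.ndarray  # bp, strictly increasing
    cumulative_cM: np.ndarray  # non-decreasing

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.cumulative_cM = np.asarray(self.cumulative_cM, dtype=np.float64)
        if self.positions.shape != self.cumulative_cM.shape:
            raise ValueError("positions and cumulative_cM must have equal length")
        if self.positions.size == 0:
            raise ValueError("genetic map must contain at least one row")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cumulative_cM) < 0):
            raise ValueError("cumulative cM must be non-decreasing")

    def cm_at(self, positions_bp: np.ndarray) -> np.ndarray:
        """Interpolated cumulative cM at arbitrary bp positions."""
        return np.interp(np.asarray(positions_bp, dtype=np.float64),
                         self.positions.astype(np.float64), self.cumulative_cM)

    @classmethod
    def constant_rate(cls, start_bp: int, end_bp: int,
                      rate_cm_per_mb: float = 1.0) -> "GeneticMap":
        """Uniform-recombination map over [start_bp, end_bp]."""
        span_cm = (end_bp - start_bp) / 1e6 * rate_cm_per_mb
        return cls(np.array([start_bp, end_bp]), np.array([0.0, span_cm]))


# ---------------------------------------------------------------------------
# hap / legend


def read_hap_legend(hap_path: str | Path, legend_path: str | Path) -> HaplotypePanel:
    """Read an IMPUTE-style reference panel from .hap + .legend files."""
    sites: list[VariantSite] = []
    with open(legend_path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{legend_path}:1: empty legend header")
        for lineno, line in enumerate(fh, start=2):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 4:
                raise FormatError(
                    f"{legend_path}:{lineno}: expected 4 columns, got {len(tok)}")
            try:
                pos = int(tok[1])
            except ValueError:
                raise FormatError(
                    f"{legend_path}:{lineno}: position {tok[1]!r} is not an integer"
                ) from None
            sites.append(VariantSite(tok[0], pos, tok[2], tok[3]))

    rows: list[np.ndarray] = []
    ncols: int | None = None
    with open(hap_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if ncols is None:
                ncols = len(tok)
            elif len(tok) != ncols:
                raise FormatError(
                    f"{hap_path}:{lineno}: expected {ncols} alleles, got {len(tok)}")
            try:
                row = np.array(tok, dtype=np.uint8)
            except ValueError:
                raise FormatError(
                    f"{hap_path}:{lineno}: non-numeric allele token") from None
            if row.size and row.max() > 1:
                raise FormatError(f"{hap_path}:{lineno}: allele token not in {{0,1}}")
            rows.append(row)

    if len(rows) != len(sites):
        raise FormatError(
            f"{hap_path}: {len(rows)} haplotype rows but legend "
            f"{legend_path} has {len(sites)} sites (first mismatch at line "
            f"{min(len(rows), len(sites)) + 1})")
    alleles = np.vstack(rows) if rows else np.zeros((0, 0), dtype=np.uint8)
    return HaplotypePanel(sites=sites, alleles=alleles)


def write_hap_legend(panel: HaplotypePanel, hap_path: str | Path,
                     legend_path: str | Path) -> None:
    with open(legend_path, "w") as fh:
        fh.write("id position a0 a1\n")
        for s in panel.sites:
            fh.write(f"{s.id} {s.position} {s.allele0} {s.allele1}\n")
    with open(hap_path, "w") as fh:
        for row in panel.alleles:
            fh.write(" ".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# gen / sample


def _parse_gen_line(tok: list[str], path: str, lineno: int
                    ) -> tuple[VariantSite, np.ndarray]:
    if len(tok) < 5 or (len(tok) - 5) % 3 != 0:
        raise FormatError(
            f"{path}:{lineno}: expected 5 leading columns plus probability "
            f"triples, got {len(tok)} tokens")
    try:
        pos = int(tok[2])
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: position {tok[2]!r} is not an integer") from None
    site = VariantSite(tok[1] if tok[1] != "." else tok[0], pos, tok[3], tok[4])
    try:
        probs = np.array(tok[5:], dtype=np.float64).reshape(-1, 3)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-numeric probability token") from None
    if (probs < 0).any():
        raise FormatError(f"{path}:{lineno}: negative genotype probability")
    return site, probs


def read_gen(gen_path: str | Path, call_threshold: float = 0.9
             ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Read a .gen file into hard genotypes plus the raw probability triples.

    A genotype is called as the argmax of its triple when that probability
    exceeds ``call_threshold``; otherwise it is missing.  Triples of (0,0,0)
    or summing below 0.1 encode missing outright.

    Returns
    -------
    (GenotypeMatrix, ndarray)
        Hard calls and the (sites x individuals x 3) probability array.
    """
    sites: list[VariantSite] = []
    triples: list[np.ndarray] = []
    n_ind: int | None = None
    path = str(gen_path)
    with open(gen_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            site, probs = _parse_gen_line(tok, path, lineno)
            if n_ind is None:
                n_ind = probs.shape[0]
            elif probs.shape[0] != n_ind:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_ind} individuals, "
                    f"got {probs.shape[0]}")
            sites.append(site)
            triples.append(probs)

    probs = (np.stack(triples) if triples
             else np.zeros((0, 0, 3), dtype=np.float64))
    sums = probs.sum(axis=2)
    calls = np.full(probs.shape[:2], MISSING, dtype=np.int8)
    if probs.size:
        best = probs.argmax(axis=2)
        bestp = probs.max(axis=2)
        ok = (sums >= 0.1) & (bestp > call_threshold)
        calls[ok] = best[ok]
    geno = GenotypeMatrix(sites=sites, genotypes=calls)
    return geno, probs


def write_gen(path: str | Path, sites: Sequence[VariantSite],
              probabilities: np.ndarray, chromosome: str = "---") -> None:
    """Write per-individual genotype-probability triples in .gen format."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    if probabilities.ndim != 3 or probabilities.shape[2] != 3:
        raise ValueError("probabilities must have shape (sites, individuals, 3)")
    if probabilities.shape[0] != len(sites):
        raise ValueError("probability rows do not match site count")
    sums = probabilities.sum(axis=2)
    nonmissing = sums >= 0.1
    if np.any(np.abs(sums[nonmissing] - 1.0) > 1e-6):
        raise ValueError("probability triples must sum to 1 within 1e-6")
    with open(path, "w") as fh:
        for site, row in zip(sites, probabilities):
            lead = f"{chromosome} {site.id} {site.position} {site.allele0} {site.allele1}"
            body = " ".join(f"{p:.6f}" for p in row.ravel())
            fh.write(f"{lead} {body}\n")


def read_sample(path: str | Path) -> list[str]:
    """Read individual IDs from a .sample file (two header lines)."""
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}:1: sample file needs two header lines")
    return [tok[0] for tok in lines[2:]]


def write_sample(path: str | Path, individual_ids: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for iid in individual_ids:
            fh.write(f"{iid} {iid} 0\n")


# ---------------------------------------------------------------------------
# genetic map


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a 3-column genetic map (position, rate cM/Mb, cumulative cM)."""
    positions: list[int] = []
    cms: list[float] = []
    seen: set[int] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}:1: empty map header")
        prev_cm = -np.inf
        for lineno, line in enumerate(fh, start=2):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(tok)}")
            try:
                pos = int(float(tok[0]))
                cm = float(tok[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric map entry") from None
            if pos in seen:  # duplicate positions: keep first
                continue
            if cm < prev_cm:
                raise FormatError(
                    f"{path}:{lineno}: cumulative cM decreases ({cm} < {prev_cm})")
            seen.add(pos)
            positions.append(pos)
            cms.append(cm)
            prev_cm = cm
    if not positions:
        raise FormatError(f"{path}:2: map has no data rows")
    return GeneticMap(np.array(positions), np.array(cms))


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position COMBINED_rate(cM/Mb) Genetic_Map(cM)\n")
        pos = gmap.positions
        cm = gmap.cumulative_cM
        for i in range(len(pos)):
            if i + 1 < len(pos):
                rate = (cm[i + 1] - cm[i]) / (pos[i + 1] - pos[i]) * 1e6
            else:
                rate = 0.0
            fh.write(f"{pos[i]} {rate:.6f} {cm[i]:.6f}\n")


# ---------------------------------------------------------------------------
# site matching


def match_sites(reference: HaplotypePanel, study: GenotypeMatrix
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align study sites to reference sites by position and allele pair.

    A study site matches a reference site when positions are identical and
    the allele pairs agree, in either order; when the order is swapped the
    study genotypes are flipped (g -> 2 - g).  Sites whose allele pairs
    conflict (including strand-ambiguous mismatches) are dropped with a
    warning.

    Returns
    -------
    (ref_index, study_index, flip)
        Parallel arrays: matched reference site indices, matched study site
        indices, and a boolean flip flag per match.
    """
    by_pos = {s.position: i for i, s in enumerate(reference.sites)}
    ref_idx: list[int] = []
    study_idx: list[int] = []
    flip: list[bool] = []
    dropped = 0
    for j, s in enumerate(study.sites):
        i = by_pos.get(s.position)
        if i is None:
            continue
        r = reference.sites[i]
        if (s.allele0, s.allele1) == (r.allele0, r.allele1):
            ref_idx.append(i); study_idx.append(j); flip.append(False)
        elif (s.allele0, s.allele1) == (r.allele1, r.allele0):
            ref_idx.append(i); study_idx.append(j); flip.append(True)
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} study sites with allele conflicts",
                      stacklevel=2)
    return (np.array(ref_idx, dtype=np.int64),
            np.array(study_idx, dtype=np.int64),
            np.array(flip, dtype=bool))
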