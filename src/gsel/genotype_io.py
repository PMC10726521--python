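"""Genotype containers, HapMap / numeric-matrix I/O, and marker QC.

Genotypes are held as additive dosages: each cell counts copies (0, 1 or 2)
of the *coded* allele at a biallelic SNP, with ``NaN`` marking missing calls.
The coded allele is, by fixed convention, the alphabetically second of the two
alleles listed for the marker; because every downstream model centers the
dosage matrix, flipping the coded allele is an affine change that leaves
predictions and accuracies invariant.

QC follows the standard panel-cleaning recipe: drop samples with low genotype
call rates first, then markers with low call rates, then markers with low
minor allele frequency (MAF computed on non-missing calls only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"

#: IUPAC single-letter heterozygote codes -> the unordered allele pair.
_IUPAC_HET = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}

_HAPMAP_META_COLS = 11  # rs#, alleles, chrom, pos, strand, assembly#, center, protLSID, assayLSID, panelLSID, QCcode


class GenotypeError(ValueError):
    """Malformed genotype input or an invalid genotype operation."""


@dataclass
class MarkerMap:
    """Physical map: chromosome label and bp position per marker.

    Positions are 1-based and must be strictly increasing within each
    chromosome once markers are grouped by chromosome in file order.
    """

    marker_ids: list[str]
    chromosomes: np.ndarray
    positions_bp: np.ndarray

    def __post_init__(self) -> None:
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        if not (len(self.marker_ids) == len(self.chromosomes) == len(self.positions_bp)):
            raise GenotypeError("marker map fields have mismatched lengths")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise GenotypeError("duplicate marker ids in map")
        if np.any(self.positions_bp < 0):
            raise GenotypeError("negative bp position in marker map")
        for chrom in pd.unique(self.chromosomes):
            pos = self.positions_bp[self.chromosomes == chrom]
            if np.any(np.diff(pos) <= 0):
                raise GenotypeError(f"positions not strictly increasing on chromosome {chrom!r}")

    def __len__(self) -> int:
        return len(self.marker_ids)

    def subset(self, marker_ids: list[str]) -> "MarkerMap":
        index = {m: i for i, m in enumerate(self.marker_ids)}
        try:
            rows = [index[m] for m in marker_ids]
        except KeyError as exc:
            raise GenotypeError(f"marker {exc.args[0]!r} not in map") from exc
        return MarkerMap(
            marker_ids=list(marker_ids),
            chromosomes=self.chromosomes[rows],
            positions_bp=self.positions_bp[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_ids, "chromosome": self.chromosomes, "position_bp": self.positions_bp}
        )


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix, values in {0, 1, 2, NaN}."""

    individual_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise GenotypeError("dosages must be a 2-D array")
        n, m = self.dosages.shape
        if n != len(self.individual_ids) or m != len(self.marker_ids):
            raise GenotypeError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.marker_ids)} markers"
            )
        # Range check only: raw calls are {0,1,2} but mean-imputed cells are fractional.
        out_of_range = np.isfinite(self.dosages) & ((self.dosages < 0) | (self.dosages > 2))
        if out_of_range.any():
            i, j = np.argwhere(out_of_range)[0]
            raise GenotypeError(
                f"dosage {self.dosages[i, j]!r} at individual "
                f"{self.individual_ids[i]!r}, marker {self.marker_ids[j]!r} is outside [0, 2]"
            )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def is_complete(self) -> bool:
        return bool(np.isfinite(self.dosages).all())

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker frequency of the coded allele, non-missing calls only."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def subset(self, individual_ids=None, marker_ids=None) -> "GenotypeMatrix":
        rows = np.arange(self.n_individuals)
        cols = np.arange(self.n_markers)
        ind_ids, mk_ids = self.individual_ids, self.marker_ids
        if individual_ids is not None:
            idx = {s: i for i, s in enumerate(self.individual_ids)}
            rows = np.array([idx[s] for s in individual_ids], dtype=int)
            ind_ids = list(individual_ids)
        if marker_ids is not None:
            idx = {m: j for j, m in enumerate(self.marker_ids)}
            cols = np.array([idx[m] for m in marker_ids], dtype=int)
            mk_ids = list(marker_ids)
        return GenotypeMatrix(ind_ids, mk_ids, self.dosages[np.ix_(rows, cols)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.individual_ids, columns=self.marker_ids)


@dataclass
class QCReport:
    """Accounting of a QC pass: every removed marker/sample with its reason."""

    n_markers_in: int
    n_markers_out: int
    n_samples_in: int
    n_samples_out: int
    removed_markers: dict[str, str] = field(default_factory=dict)  # marker_id -> "maf" | "marker_call_rate"
    removed_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_markers_in == self.n_markers_out + len(self.removed_markers)
        assert self.n_samples_in == self.n_samples_out + len(self.removed_samples)

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", s, "sample_call_rate") for s in self.removed_samples]
        rows += [("marker", m, reason) for m, reason in self.removed_markers.items()]
        return pd.DataFrame(rows, columns=["axis", "id", "reason"])


# ---------------------------------------------------------------------------
# HapMap
# ---------------------------------------------------------------------------

def _decode_call(call: str, alleles: tuple[str, str], coded: str) -> float:
    """One HapMap genotype call -> dosage of the coded allele (NaN if unresolvable)."""
    call = call.strip()
    if not call or call in ("NN", "N", MISSING_TOKEN, "--", "./."):
        return np.nan
    if len(call) == 1:
        pair = _IUPAC_HET.get(call)
        if pair is not None:
            if pair == frozenset(alleles):
                return 1.0
            return np.nan
        if call in alleles:  # homozygote in single-letter form
            return 2.0 if call == coded else 0.0
        return np.nan
    if len(call) == 2:
        a, b = call[0], call[1]
        if a in alleles and b in alleles:
            return float((a == coded) + (b == coded))
    return np.nan


def read_hapmap(path, max_bad_call_fraction: float = 0.1):
    """Read a HapMap-dialect table into a (GenotypeMatrix, MarkerMap) pair.

    The dialect: 11 metadata columns (rs#, alleles, chrom, pos, ...) then one
    column per individual; calls are two-letter allele pairs or IUPAC codes.
    Heterozygotes map to 1; the homozygote of the alphabetically second listed
    allele to 2, the first to 0.  Unknown codes are collected and treated as
    missing, erroring out if they exceed ``max_bad_call_fraction`` of calls.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) <= _HAPMAP_META_COLS:
            raise GenotypeError(f"HapMap header has {len(header)} columns; expected > {_HAPMAP_META_COLS}")
        if header[0] not in ("rs#", "rs"):
            raise GenotypeError(f"unexpected HapMap header start {header[0]!r}")
        sample_ids = header[_HAPMAP_META_COLS:]

        marker_ids: list[str] = []
        chroms: list[str] = []
        positions: list[int] = []
        rows: list[np.ndarray] = []
        n_bad = 0
        n_calls = 0
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise GenotypeError(f"line {lineno}: {len(fields)} columns, header has {len(header)}")
            marker_ids.append(fields[0])
            allele_field = fields[1].replace("/", "")
            if len(allele_field) != 2:
                raise GenotypeError(f"line {lineno}: cannot parse alleles {fields[1]!r}")
            alleles = (allele_field[0], allele_field[1])
            coded = max(alleles)  # alphabetically second allele is counted
            chroms.append(fields[2])
            positions.append(int(fields[3]))
            calls = fields[_HAPMAP_META_COLS:]
            row = np.array([_decode_call(c, alleles, coded) for c in calls])
            explicit_missing = [c in ("NN", "N", MISSING_TOKEN, "--", "./.", "") for c in calls]
            n_bad += int(np.sum(np.isnan(row) & ~np.array(explicit_missing)))
            n_calls += len(calls)
            rows.append(row)

    if n_calls and n_bad / n_calls > max_bad_call_fraction:
        raise GenotypeError(f"{n_bad}/{n_calls} genotype calls unresolvable (cap {max_bad_call_fraction:.0%})")

    dosages = np.vstack(rows).T if rows else np.empty((len(sample_ids), 0))
    geno = GenotypeMatrix(sample_ids, marker_ids, dosages)
    gmap = MarkerMap(marker_ids, np.array(chroms, dtype=object), np.array(positions))
    return geno, gmap


def write_hapmap(geno: GenotypeMatrix, gmap: MarkerMap, path, alleles: dict[str, tuple[str, str]] | None = None) -> None:
    """Write a HapMap-dialect file; synthetic A/G alleles unless given."""
    if gmap.marker_ids != geno.marker_ids:
        gmap = gmap.subset(geno.marker_ids)
    meta_fill = ["+", "NA", "NA", "NA", "NA", "NA", "NA"]
    with open(path, "w") as fh:
        fh.write(
            "\t".join(
                ["rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
                 "protLSID", "assayLSID", "panelLSID", "QCcode"] + geno.individual_ids
            )
            + "\n"
        )
        for j, marker in enumerate(geno.marker_ids):
            a1, a2 = (alleles or {}).get(marker, ("A", "G"))
            lo, hi = min(a1, a2), max(a1, a2)  # hi is the coded allele
            calls = []
            for d in geno.dosages[:, j]:
                if not np.isfinite(d):
                    calls.append("NN")
                elif d == 0:
                    calls.append(lo + lo)
                elif d == 1:
                    calls.append(lo + hi)
                else:
                    calls.append(hi + hi)
            fh.write(
                "\t".join(
                    [marker, f"{a1}/{a2}", str(gmap.chromosomes[j]), str(gmap.positions_bp[j])]
                    + meta_fill
                    + calls
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Numeric matrix
# ---------------------------------------------------------------------------

def read_numeric(path) -> GenotypeMatrix:
    """Read a tab-delimited dosage matrix (header of marker ids, first column individual id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN], keep_default_na=False, dtype=str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            if raw is np.nan or (isinstance(raw, float) and np.isnan(raw)):
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise GenotypeError(
                    f"non-numeric dosage {raw!r} at individual {df.index[i]!r}, marker {col!r}"
                ) from None
    # Range validation (0 <= d <= 2, fractional imputed values allowed) happens
    # in the constructor, which names the offending individual/marker.
    return GenotypeMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_numeric(geno: GenotypeMatrix, path) -> None:
    df = geno.to_frame()
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, float_format="%.17g")


# ---------------------------------------------------------------------------
# QC + imputation
# ---------------------------------------------------------------------------

def qc_filter(
    geno: GenotypeMatrix,
    maf_min: float = 0.01,
    marker_call_rate_min: float = 0.95,
    sample_call_rate_min: float = 0.50,
):
    """Apply panel QC: sample call rate, then marker call rate, then MAF.

    Thresholds are exclusive: a marker with MAF exactly ``maf_min`` or call
    rate exactly ``marker_call_rate_min`` is retained.  Returns the filtered
    matrix and a :class:`QCReport` accounting for every removal.
    """
    if geno.n_individuals == 0 or geno.n_markers == 0:
        raise GenotypeError("empty genotype matrix")

    observed = np.isfinite(geno.dosages)

    sample_rate = observed.mean(axis=1)
    keep_samples = sample_rate >= sample_call_rate_min
    removed_samples = [s for s, k in zip(geno.individual_ids, keep_samples) if not k]
    if not keep_samples.any():
        raise GenotypeError("QC removed every sample")

    dos = geno.dosages[keep_samples]
    observed = observed[keep_samples]

    marker_rate = observed.mean(axis=0)
    keep_rate = marker_rate >= marker_call_rate_min

    with np.errstate(invalid="ignore"):
        p = np.nansum(dos, axis=0) / (2.0 * np.maximum(observed.sum(axis=0), 1))
    maf = np.minimum(p, 1.0 - p)
    maf[observed.sum(axis=0) == 0] = 0.0
    keep_maf = maf >= maf_min

    removed_markers: dict[str, str] = {}
    for j, marker in enumerate(geno.marker_ids):
        if not keep_rate[j]:
            removed_markers[marker] = "marker_call_rate"
        elif not keep_maf[j]:
            removed_markers[marker] = "maf"
    keep_markers = keep_rate & keep_maf
    if not keep_markers.any():
        raise GenotypeError("QC removed every marker")

    out = GenotypeMatrix(
        [s for s, k in zip(geno.individual_ids, keep_samples) if k],
        [m for m, k in zip(geno.marker_ids, keep_markers) if k],
        dos[:, keep_markers],
    )
    report = QCReport(
        n_markers_in=geno.n_markers,
        n_markers_out=out.n_markers,
        n_samples_in=geno.n_individuals,
        n_samples_out=out.n_individuals,
        removed_markers=removed_markers,
        removed_samples=removed_samples,
    )
    return out, report


def impute_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing cells by the per-marker mean dosage (non-missing calls).

    Imputed values are generally fractional; they are stored as-is since every
    consumer treats dosages as real-valued covariates.
    """
    dos = geno.dosages.copy()
    observed = np.isfinite(dos)
    n_obs = observed.sum(axis=0)
    if np.any(n_obs == 0):
        j = int(np.argmin(n_obs))
        raise GenotypeError(f"marker {geno.marker_ids[j]!r} has no observed calls; run QC first")
    if observed.all():
        return geno
    col_mean = np.nansum(dos, axis=0) / n_obs
    miss_i, miss_j = np.where(~observed)
    dos[miss_i, miss_j] = col_mean[miss_j]
    return GenotypeMatrix(list(geno.individual_ids), list(geno.marker_ids), dos)
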