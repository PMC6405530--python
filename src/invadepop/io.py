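"""Genotype and sample-metadata input/output.

Two plain-text genotype dialects are supported:

* a STRUCTURE-style file with two whitespace-delimited allele rows per
  diploid individual (missing code ``-9``, optional single header row of
  locus names), and
* a CSV table with one row per individual and one column per locus holding
  the alternate-allele count (``0``/``1``/``2``/``NA``).

Genotypes are held as counts of the designated alternate allele; per locus
the alternate allele is the lexicographically larger of the (at most two)
symbols observed in the file, which makes the encoding deterministic
without an external reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid call.  Kept distinct from 0, which is a
#: valid homozygous-reference count.
MISSING: int = -1

RANGE_LABELS = ("native", "invasive")
SOURCE_TYPES = ("natural", "common_garden", "lab_seedling")

METADATA_COLUMNS = (
    "individual_id",
    "population",
    "range_label",
    "longitude",
    "latitude",
    "source_type",
)


class FormatError(ValueError):
    """A genotype or metadata file violates its dialect."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci, encoded as alternate-allele counts.

    Parameters
    ----------
    individual_ids, locus_ids
        Ordered, unique identifiers for rows and columns of ``calls``.
    calls
        ``int8`` array of shape ``(n_individuals, n_loci)`` with entries in
        ``{0, 1, 2}`` or :data:`MISSING`.
    allele_labels
        Per-locus ``(ref, alt)`` symbol pair.  ``alt`` is the allele being
        counted.  Defaults to ``("1", "2")`` per locus.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    allele_labels: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise FormatError("duplicate individual IDs")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise FormatError("duplicate locus IDs")
        if self.calls.shape != (len(self.individual_ids), len(self.locus_ids)):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        valid = (self.calls == MISSING) | ((self.calls >= 0) & (self.calls <= 2))
        if not valid.all():
            raise FormatError("genotype calls must be 0, 1, 2 or missing")
        if not self.allele_labels:
            self.allele_labels = [("1", "2") for _ in self.locus_ids]
        if len(self.allele_labels) != len(self.locus_ids):
            raise FormatError("allele_labels length does not match locus count")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        """Boolean array, True where the call is missing."""
        return self.calls == MISSING

    def subset(self, individuals=None, loci=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given individuals/loci.

        Arguments may be ID lists or boolean/integer indexers; order of the
        given IDs is preserved.
        """
        ind_idx = _resolve_index(individuals, self.individual_ids)
        loc_idx = _resolve_index(loci, self.locus_ids)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in ind_idx],
            [self.locus_ids[j] for j in loc_idx],
            self.calls[np.ix_(ind_idx, loc_idx)],
            [self.allele_labels[j] for j in loc_idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Calls as a DataFrame (missing as pandas NA)."""
        arr = self.calls.astype("float64")
        arr[arr == MISSING] = np.nan
        df = pd.DataFrame(arr, index=self.individual_ids, columns=self.locus_ids)
        return df.astype("Int64")


def _resolve_index(sel, ids: list[str]) -> list[int]:
    if sel is None:
        return list(range(len(ids)))
    sel = list(sel)
    if len(sel) > 0 and isinstance(sel[0], (bool, np.bool_)):
        return [i for i, keep in enumerate(sel) if keep]
    if len(sel) > 0 and isinstance(sel[0], (int, np.integer)):
        return [int(i) for i in sel]
    lookup = {name: i for i, name in enumerate(ids)}
    missing = [s for s in sel if s not in lookup]
    if missing:
        raise KeyError(f"unknown IDs: {missing[:5]}")
    return [lookup[s] for s in sel]


# ---------------------------------------------------------------------------
# STRUCTURE dialect
# ---------------------------------------------------------------------------

def read_structure_file(
    path,
    ploidy_rows: int = 2,
    missing_code: str = "-9",
    header: bool = True,
) -> GenotypeMatrix:
    """Read a two-row-per-individual STRUCTURE genotype file.

    Each individual occupies ``ploidy_rows`` consecutive whitespace-delimited
    rows: an individual label followed by one allele symbol per locus.  The
    alternate allele per locus is the lexicographically larger observed
    symbol; a call is missing if either row carries ``missing_code``.
    """
    if ploidy_rows != 2:
        raise FormatError("only diploid (two-row) STRUCTURE files are supported")
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    if header:
        locus_ids = lines[0]
        data = lines[1:]
    else:
        locus_ids = [f"L{j + 1}" for j in range(len(lines[0]) - 1)]
        data = lines
    if len(data) % 2 != 0:
        raise FormatError(f"{path}: odd number of data rows ({len(data)})")
    n_loci = len(locus_ids)
    for k, row in enumerate(data):
        if len(row) != n_loci + 1:
            line_no = k + (2 if header else 1)
            raise FormatError(
                f"{path}: line {line_no} has {len(row)} fields, expected {n_loci + 1}"
            )

    individual_ids: list[str] = []
    rows_a: list[list[str]] = []
    rows_b: list[list[str]] = []
    for k in range(0, len(data), 2):
        if data[k][0] != data[k + 1][0]:
            raise FormatError(
                f"{path}: row pair for individual {data[k][0]!r} has mismatched label "
                f"{data[k + 1][0]!r}"
            )
        individual_ids.append(data[k][0])
        rows_a.append(data[k][1:])
        rows_b.append(data[k + 1][1:])

    n_ind = len(individual_ids)
    calls = np.full((n_ind, n_loci), MISSING, dtype=np.int8)
    allele_labels: list[tuple[str, str]] = []
    for j in range(n_loci):
        symbols = sorted(
            ({r[j] for r in rows_a} | {r[j] for r in rows_b}) - {missing_code}
        )
        if len(symbols) > 2:
            raise FormatError(
                f"{path}: locus {locus_ids[j]!r} shows {len(symbols)} allele "
                f"symbols ({symbols}); at most two allowed"
            )
        if not symbols:
            ref, alt = "1", "2"  # fully missing locus
        elif len(symbols) == 1:
            # monomorphic: single symbol counted as reference (count 0)
            ref = alt = symbols[0]
        else:
            ref, alt = symbols[0], symbols[1]
        allele_labels.append((ref, alt))
        for i in range(n_ind):
            a, b = rows_a[i][j], rows_b[i][j]
            if a == missing_code or b == missing_code:
                continue
            calls[i, j] = int(a == alt) + int(b == alt) if ref != alt else 0
    return GenotypeMatrix(individual_ids, locus_ids, calls, allele_labels)


def write_structure_file(gm: GenotypeMatrix, path, missing_code: str = "-9") -> None:
    """Write the two-row STRUCTURE dialect read by :func:`read_structure_file`."""
    with open(path, "w") as fh:
        fh.write(" ".join(gm.locus_ids) + "\n")
        for i, ind in enumerate(gm.individual_ids):
            row_a, row_b = [ind], [ind]
            for j in range(gm.n_loci):
                ref, alt = gm.allele_labels[j]
                c = int(gm.calls[i, j])
                if c == MISSING:
                    row_a.append(missing_code)
                    row_b.append(missing_code)
                else:
                    # write alt copies first; reader is order-insensitive
                    row_a.append(alt if c >= 1 else ref)
                    row_b.append(alt if c == 2 else ref)
            fh.write(" ".join(row_a) + "\n")
            fh.write(" ".join(row_b) + "\n")


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def read_genotype_csv(path) -> GenotypeMatrix:
    """Read the CSV dialect: ``individual_id`` column then one 0/1/2/NA column per locus."""
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: no locus columns found")
    first = df.columns[0]
    if first != "individual_id":
        raise FormatError(
            f"{path}: first column must be 'individual_id', found {first!r}"
        )
    locus_ids = list(df.columns[1:])
    body = df[locus_ids]
    calls = np.full(body.shape, MISSING, dtype=np.int8)
    for j, col in enumerate(locus_ids):
        vals = body[col]
        ok = vals.isna() | vals.isin([0, 1, 2, "0", "1", "2"])
        if not ok.all():
            bad = vals[~ok].iloc[0]
            raise FormatError(
                f"{path}: locus {col!r} contains invalid genotype value {bad!r}"
            )
        present = ~vals.isna()
        calls[present.to_numpy(), j] = vals[present].astype(int).to_numpy()
    return GenotypeMatrix(list(df[first]), locus_ids, calls)


def write_genotype_csv(gm: GenotypeMatrix, path) -> None:
    gm.to_frame().rename_axis("individual_id").to_csv(path)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a metadata table in place and return it.

    Checks column presence, coordinate ranges, label vocabularies, ID
    uniqueness, and that each population maps to a single range.
    """
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"metadata missing columns: {missing_cols}")
    meta = meta.copy()
    meta["individual_id"] = meta["individual_id"].astype(str)
    meta["population"] = meta["population"].astype(str)
    if meta["individual_id"].duplicated().any():
        dups = meta.loc[meta["individual_id"].duplicated(), "individual_id"].tolist()
        raise FormatError(f"duplicate individual IDs in metadata: {dups[:5]}")
    bad_range = set(meta["range_label"]) - set(RANGE_LABELS)
    if bad_range:
        raise FormatError(f"unknown range_label values: {sorted(bad_range)}")
    bad_src = set(meta["source_type"]) - set(SOURCE_TYPES)
    if bad_src:
        raise FormatError(f"unknown source_type values: {sorted(bad_src)}")
    lat = meta["latitude"].astype(float)
    lon = meta["longitude"].astype(float)
    if ((lat < -90) | (lat > 90)).any():
        off = meta.loc[(lat < -90) | (lat > 90), "individual_id"].tolist()
        raise FormatError(f"latitude outside [-90, 90] for: {off[:5]}")
    if ((lon < -180) | (lon > 180)).any():
        off = meta.loc[(lon < -180) | (lon > 180), "individual_id"].tolist()
        raise FormatError(f"longitude outside [-180, 180] for: {off[:5]}")
    ranges_per_pop = meta.groupby("population")["range_label"].nunique()
    multi = ranges_per_pop[ranges_per_pop > 1].index.tolist()
    if multi:
        raise FormatError(f"populations mapped to more than one range: {multi}")
    return meta


def read_metadata_csv(path) -> pd.DataFrame:
    """Read and validate a sample-metadata CSV (see :data:`METADATA_COLUMNS`)."""
    return validate_metadata(pd.read_csv(path))


def write_metadata_csv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def check_join(gm: GenotypeMatrix, meta: pd.DataFrame) -> None:
    """Raise if any genotyped individual lacks exactly one metadata row."""
    known = set(meta["individual_id"])
    orphans = [i for i in gm.individual_ids if i not in known]
    if orphans:
        raise FormatError(
            f"{len(orphans)} genotyped individuals missing from metadata: {orphans[:5]}"
        )


def metadata_for(gm: GenotypeMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Metadata rows aligned to ``gm.individual_ids`` order."""
    check_join(gm, meta)
    indexed = meta.set_index("individual_id")
    out = indexed.loc[gm.individual_ids].reset_index()
    return out
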