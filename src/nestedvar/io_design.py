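"""Tabular I/O and the nested experimental design.

The experiment layout is a balanced binary nesting of depth four:
two conditions (e.g. growth on glucose G vs ethanol E), two biological
replicates per condition, two library/labelling preparations per
biological replicate, and two chips (microarray) or lanes (sequencing)
per preparation — 16 samples per platform, with the condition and
biological stages shared between platforms.

All tabular formats are plain TSV (UTF-8, '.' decimal separator, no
quoting); lines starting with '#' are metadata and are ignored on read.
Gene identifiers are opaque strings matched by exact equality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "MatrixParseError",
    "NestedDesign",
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "canonical_design",
    "read_design",
    "write_design",
    "read_matrix",
    "write_matrix",
    "read_gmt",
]

DESIGN_COLUMNS = ["sample", "condition", "biological", "preparation", "unit"]

PLATFORMS = ("counts", "logratio", "logintensity")


class DesignError(ValueError):
    """Raised when a design table violates the nested-design invariants."""


class MatrixParseError(ValueError):
    """Raised when an expression matrix file cannot be parsed."""


@dataclass(frozen=True)
class NestedDesign:
    """A validated nested design mapping samples to their factor levels.

    Parameters
    ----------
    table
        DataFrame with columns ``sample, condition, biological,
        preparation, unit``; one row per sample, in sample order.
    strict
        If True (default), require the canonical 2/2/2/2 structure with
        16 samples.  If False, any balanced design with two conditions
        and a constant branching factor at every level is accepted.
    """

    table: pd.DataFrame
    strict: bool = True

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise DesignError(f"design table missing columns: {missing}")
        object.__setattr__(
            self, "table", t[DESIGN_COLUMNS].reset_index(drop=True).astype(str)
        )
        self._validate()

    def _validate(self) -> None:
        t = self.table
        if t["sample"].duplicated().any():
            dups = t.loc[t["sample"].duplicated(), "sample"].tolist()
            raise DesignError(f"duplicate sample ids: {dups}")
        # nesting must be a tree: each child label has exactly one parent
        for child, parent in [
            ("biological", "condition"),
            ("preparation", "biological"),
            ("unit", "preparation"),
        ]:
            parents = t.groupby(child)[parent].nunique()
            bad = parents[parents > 1]
            if len(bad):
                raise DesignError(
                    f"{child} level(s) {bad.index.tolist()} span multiple "
                    f"{parent} levels: nesting is not a tree"
                )
        n_cond = t["condition"].nunique()
        if n_cond != 2:
            raise DesignError(f"expected exactly 2 conditions, found {n_cond}")
        # balance: constant branching factor at every level of the tree
        branch = {}
        for child, parent in [
            ("biological", "condition"),
            ("preparation", "biological"),
            ("unit", "preparation"),
        ]:
            counts = t.drop_duplicates([parent, child]).groupby(parent)[child].size()
            if counts.nunique() != 1:
                raise DesignError(
                    f"unbalanced nesting at level '{child}': counts per "
                    f"{parent} are {dict(counts)}"
                )
            branch[child] = int(counts.iloc[0])
        # every (preparation, unit) pair is a single sample
        per_unit = t.groupby(["preparation", "unit"]).size()
        if (per_unit != 1).any():
            raise DesignError("each (preparation, unit) pair must be one sample")
        if self.strict:
            expect = {"biological": 2, "preparation": 2, "unit": 2}
            if branch != expect or len(t) != 16:
                raise DesignError(
                    f"strict mode requires the 2/2/2/2 design with 16 samples; "
                    f"got branching {branch} with {len(t)} samples "
                    f"(pass strict=False to relax)"
                )

    # -- convenient accessors -------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    @property
    def conditions(self) -> list[str]:
        """The two condition labels, sorted."""
        return sorted(self.table["condition"].unique())

    def condition_of(self) -> pd.Series:
        return self.table.set_index("sample")["condition"]

    def codes(self, level: str) -> np.ndarray:
        """Integer group codes for samples at a nesting level."""
        return pd.factorize(self.table[level])[0]

    def unit_index_within_preparation(self) -> pd.Series:
        """1-based position of each sample's unit within its preparation.

        Used to split the design into 'first chip/lane' vs 'second
        chip/lane' subsets for within-platform replicate comparisons.
        """
        t = self.table
        idx = t.groupby("preparation")["unit"].rank(method="dense").astype(int)
        return pd.Series(idx.values, index=t["sample"].values, name="unit_index")


def canonical_design(conditions: tuple[str, str] = ("G", "E")) -> NestedDesign:
    """The 16-sample 2x2x2x2 design used on both platforms."""
    rows = []
    for cond in conditions:
        for b in (1, 2):
            bio = f"{cond}{b}"
            for p in (1, 2):
                prep = f"{bio}P{p}"
                for u in (1, 2):
                    unit = f"{prep}U{u}"
                    rows.append((unit, cond, bio, prep, unit))
    return NestedDesign(pd.DataFrame(rows, columns=DESIGN_COLUMNS))


@dataclass
class ExpressionMatrix:
    """A gene x sample matrix with a platform tag and per-gene intensity.

    ``platform`` is one of ``counts`` (nonnegative integers), ``logratio``
    (two-channel log2(red/green) ratios) or ``logintensity``.  ``intensity``
    is a per-gene abundance summary: by default the row sum of counts
    (total reads mapping to the gene) or, for arrays, the mean cy5
    fluorescence supplied alongside the ratios.
    """

    values: pd.DataFrame
    platform: str
    intensity: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}")
        v = self.values
        if v.index.duplicated().any():
            raise MatrixParseError(
                f"duplicate gene ids: {v.index[v.index.duplicated()].tolist()}"
            )
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise MatrixParseError("matrix contains non-numeric values")
        if not np.all(np.isfinite(arr)):
            raise MatrixParseError("matrix contains missing or non-finite values")
        if self.platform == "counts":
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise MatrixParseError(
                    "platform=counts requires nonnegative integer values"
                )
            self.values = v.astype(np.int64)
        if self.intensity is None:
            if self.platform == "counts":
                self.intensity = self.values.sum(axis=1).astype(float)
            else:
                raise ValueError(
                    f"platform={self.platform} requires an explicit per-gene intensity"
                )
        else:
            self.intensity = pd.Series(self.intensity, dtype=float)
            if not self.intensity.index.equals(v.index):
                self.intensity = self.intensity.reindex(v.index)
            if self.intensity.isna().any():
                raise ValueError("intensity missing for some genes")
            if (self.intensity < 0).any():
                raise ValueError("intensity must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[genes], self.platform, self.intensity.loc[genes]
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


# -- readers / writers --------------------------------------------------------


def read_matrix(path, platform: str, intensity_col: str | None = None) -> ExpressionMatrix:
    """Read a gene x sample TSV into an :class:`ExpressionMatrix`.

    The first column holds gene ids, the header row sample ids.  For
    ``platform='counts'`` every cell must be a nonnegative integer and
    the default intensity is the per-gene row sum.  For array data pass
    ``intensity_col`` naming the column that carries the per-gene mean
    cy5 intensity; it is removed from the sample columns.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    num = df.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        r, c = np.argwhere(num.isna().to_numpy())[0]
        raise MatrixParseError(
            f"non-numeric value {df.iat[r, c]!r} at gene {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    intensity = None
    if intensity_col is None and platform != "counts" and "intensity" in num.columns:
        intensity_col = "intensity"  # convention used by write_matrix
    if intensity_col is not None:
        if intensity_col not in num.columns:
            raise MatrixParseError(f"intensity column {intensity_col!r} not found")
        intensity = num[intensity_col]
        num = num.drop(columns=[intensity_col])
    if platform == "counts":
        arr = num.to_numpy()
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            bad = np.argwhere(~np.isclose(arr, np.round(arr)) | (arr < 0))[0]
            raise MatrixParseError(
                f"non-integer count at gene {num.index[bad[0]]!r}, "
                f"column {num.columns[bad[1]]!r}"
            )
    num.index = num.index.astype(str)
    num.columns = num.columns.astype(str)
    return ExpressionMatrix(num, platform, intensity)


def _metadata_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_matrix(matrix: ExpressionMatrix, path, meta: dict | None = None) -> None:
    """Write a matrix as TSV; integer counts exactly, reals to 12 digits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_lines(meta))
        if matrix.platform == "counts":
            matrix.values.to_csv(fh, sep="\t", index_label="gene")
        else:
            out = matrix.values.copy()
            out["intensity"] = matrix.intensity
            out.to_csv(fh, sep="\t", float_format="%.12g", index_label="gene")


def read_design(path, strict: bool = True) -> NestedDesign:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return NestedDesign(df, strict=strict)


def write_design(design: NestedDesign, path, meta: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_lines(meta))
        design.table.to_csv(fh, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT v1 gene-set file (name, description, members...)."""
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                warnings.warn(
                    f"gene set {name!r}: {len(members) - len(uniq)} duplicate "
                    f"member(s) removed",
                    stacklevel=2,
                )
            sets[name] = GeneSet(name, desc, tuple(uniq))
    return GeneSetCollection(sets)
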