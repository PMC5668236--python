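"""Feature-table, taxonomy and phenotype containers.

Holds the three tabular inputs of a 16S association study — an OTU (or
taxon) count table, a Greengenes-style taxonomy map and a serum phenotype
table — together with the standard pre-association transforms: rarefaction
to a common library size, conversion to relative abundance, prevalence and
mean-abundance filtering, taxonomic aggregation, the Firmicutes/Bacteroidetes
ratio, and the derived serum lipid indices AI = (TC - HDL)/HDL and LDL/HDL.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "Lineage",
    "TaxonomyMap",
    "OtuTable",
    "PhenotypeTable",
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
    "read_phenotypes",
    "rarefy",
    "to_relative_abundance",
    "filter_features",
    "aggregate_taxa",
    "fb_ratio",
    "derive_lipid_indices",
    "AGGREGATION_RANKS",
    "TRAIT_COLUMNS",
    "DERIVED_TRAITS",
    "UNASSIGNED",
]


class ValidationError(ValueError):
    """An input violates a container invariant (duplicate ids, negative counts...)."""


class ParseError(ValueError):
    """A file cell could not be parsed; the message names the row and column."""


UNASSIGNED = "unassigned"

RANK_PREFIXES = (
    ("k__", "kingdom"),
    ("p__", "phylum"),
    ("c__", "class"),
    ("o__", "order"),
    ("f__", "family"),
    ("g__", "genus"),
    ("s__", "species"),
)
PREFIX_OF = {rank: prefix for prefix, rank in RANK_PREFIXES}
RANK_OF = {prefix: rank for prefix, rank in RANK_PREFIXES}
AGGREGATION_RANKS = ("phylum", "class", "order", "family", "genus")

TRAIT_COLUMNS = ("GLU", "TCHOL", "TG", "HDL", "LDL")
DERIVED_TRAITS = ("LDL_HDL", "AI")


class Lineage:
    """One Greengenes-style lineage, e.g. ``k__Bacteria;p__Firmicutes;...;g__``.

    Ranks carry ``k__``/``p__``/... prefixes; an empty label after the prefix
    means the rank is unassigned. Parsing is lossless up to whitespace:
    :meth:`to_string` reproduces the input string with whitespace stripped.
    """

    __slots__ = ("_tokens",)

    def __init__(self, tokens: Iterable[tuple[str, str]]):
        self._tokens = tuple((str(p), str(l)) for p, l in tokens)
        for prefix, _ in self._tokens:
            if prefix not in RANK_OF:
                raise ValidationError(f"unknown rank prefix {prefix!r}")

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        tokens = []
        for part in str(text).split(";"):
            part = part.strip()
            if not part:
                continue
            prefix = part[:3]
            if prefix not in RANK_OF:
                raise ValidationError(
                    f"lineage token {part!r} lacks a k__/p__/c__/o__/f__/g__/s__ prefix"
                )
            tokens.append((prefix, part[3:]))
        return cls(tokens)

    def to_string(self) -> str:
        return ";".join(prefix + label for prefix, label in self._tokens)

    def get(self, rank: str) -> str:
        """Label at ``rank`` (e.g. ``'genus'``), or ``'unassigned'`` when the
        rank is missing or empty."""
        prefix = PREFIX_OF.get(rank)
        if prefix is None:
            raise ValidationError(f"unknown rank {rank!r}")
        for p, label in self._tokens:
            if p == prefix:
                return label if label else UNASSIGNED
        return UNASSIGNED

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Lineage({self.to_string()!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, Lineage) and self._tokens == other._tokens

    def __hash__(self) -> int:
        return hash(self._tokens)


class TaxonomyMap(Mapping):
    """Mapping of feature id -> :class:`Lineage`."""

    def __init__(self, mapping: Mapping[str, Lineage]):
        self._map = dict(mapping)
        for fid, lin in self._map.items():
            if not isinstance(lin, Lineage):
                raise ValidationError(f"taxonomy for {fid!r} is not a Lineage")

    @classmethod
    def from_strings(cls, mapping: Mapping[str, str]) -> "TaxonomyMap":
        return cls({fid: Lineage.from_string(s) for fid, s in mapping.items()})

    def __getitem__(self, key):
        return self._map[key]

    def __iter__(self):
        return iter(self._map)

    def __len__(self):
        return len(self._map)

    def label(self, feature_id: str, rank: str) -> str:
        """Rank label for a feature; unknown features are 'unassigned'."""
        lin = self._map.get(feature_id)
        return UNASSIGNED if lin is None else lin.get(rank)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("feature_id\ttaxonomy\n")
            for fid, lin in self._map.items():
                fh.write(f"{fid}\t{lin.to_string()}\n")


def read_taxonomy(path) -> TaxonomyMap:
    """Read a 2-column TSV of feature id and lineage string."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: taxonomy file needs two columns (id, lineage)")
    ids = frame.iloc[:, 0]
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].tolist()
        raise ValidationError(f"duplicate feature ids in taxonomy: {dups}")
    return TaxonomyMap.from_strings(dict(zip(ids, frame.iloc[:, 1])))


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dups}")


class OtuTable:
    """Features x samples abundance matrix.

    Parameters
    ----------
    data
        DataFrame with feature ids as index and sample ids as columns, or
        anything :class:`pandas.DataFrame` accepts.
    kind
        ``'counts'`` (non-negative, typically integer) or
        ``'relative_abundance'`` (columns sum to 1).
    taxonomy
        Optional :class:`TaxonomyMap` carried alongside (e.g. split off a
        BIOM-TSV taxonomy column).
    """

    REL_TOL = 1e-9

    def __init__(self, data, kind: str = "counts", taxonomy: TaxonomyMap | None = None):
        frame = pd.DataFrame(data)
        _check_unique(frame.index, "feature")
        _check_unique(frame.columns, "sample")
        values = frame.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("feature table contains non-finite values")
        if (values < 0).any():
            raise ValidationError("feature table contains negative values")
        if kind not in ("counts", "relative_abundance"):
            raise ValidationError(f"unknown table kind {kind!r}")
        if kind == "relative_abundance":
            sums = values.sum(axis=0)
            bad = np.abs(sums - 1.0) > self.REL_TOL
            if bad.any():
                raise ValidationError(
                    "relative-abundance columns do not sum to 1: "
                    f"{list(frame.columns[bad])[:5]}"
                )
        self.data = frame
        self.kind = kind
        self.taxonomy = taxonomy

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.data.loc[:, list(sample_ids)], kind=self.kind,
                        taxonomy=self.taxonomy)

    def copy(self) -> "OtuTable":
        return OtuTable(self.data.copy(), kind=self.kind, taxonomy=self.taxonomy)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<OtuTable {self.n_features} features x {self.n_samples} samples, {self.kind}>"

    # -- transforms ------------------------------------------------------
    def relative_abundance(self) -> "OtuTable":
        """Per-sample closure to proportions; idempotent."""
        if self.kind == "relative_abundance":
            return self
        sums = self.values.sum(axis=0)
        zero = sums <= 0
        if zero.any():
            raise ValidationError(
                f"all-zero sample columns: {list(self.data.columns[np.flatnonzero(zero)])}"
            )
        frame = self.data / sums
        return OtuTable(frame, kind="relative_abundance", taxonomy=self.taxonomy)

    def rarefy(self, depth: int, seed=None, drop_low: bool = False) -> "OtuTable":
        """Subsample each sample column without replacement to ``depth`` tags.

        Columns shallower than ``depth`` raise unless ``drop_low`` is set, in
        which case they are dropped with a warning naming them. Deterministic
        given ``seed`` (multivariate hypergeometric per sample, samples drawn
        in column order).
        """
        if self.kind != "counts":
            raise ValidationError("rarefy requires a counts table")
        depth = int(depth)
        if depth < 1:
            raise ValidationError("rarefaction depth must be >= 1")
        vals = self.values
        rounded = np.rint(vals)
        if not np.allclose(vals, rounded, atol=1e-6):
            raise ValidationError("rarefy requires integer counts")
        counts = rounded.astype(np.int64)
        sums = counts.sum(axis=0)
        shallow = sums < depth
        if shallow.any():
            offending = [str(c) for c in self.data.columns[shallow]]
            if not drop_low:
                raise ValidationError(
                    f"samples below rarefaction depth {depth}: {offending}"
                )
            warnings.warn(
                f"dropping {len(offending)} samples below depth {depth}: {offending}",
                stacklevel=2,
            )
        keep = ~shallow
        rng = np.random.default_rng(seed)
        out = np.empty((self.n_features, int(keep.sum())), dtype=np.int64)
        j = 0
        for i in range(self.n_samples):
            if not keep[i]:
                continue
            col = counts[:, i]
            if sums[i] == depth:
                out[:, j] = col
            else:
                out[:, j] = rng.multivariate_hypergeometric(col, depth)
            j += 1
        frame = pd.DataFrame(out, index=self.data.index,
                             columns=self.data.columns[keep])
        return OtuTable(frame, kind="counts", taxonomy=self.taxonomy)

    def filter_features(
        self,
        min_mean_rel_abund: float,
        min_prevalence: float,
        abundance_mode: str = "mean",
    ) -> tuple["OtuTable", pd.DataFrame]:
        """Keep features with mean relative abundance >= ``min_mean_rel_abund``
        (zeros included; ``abundance_mode='max'`` switches to the per-sample
        maximum) AND prevalence >= ``min_prevalence``.

        Returns the filtered table (same kind as the input) and a per-feature
        report with the computed criteria and kept flags.
        """
        for name, thr in (("min_mean_rel_abund", min_mean_rel_abund),
                          ("min_prevalence", min_prevalence)):
            if not 0.0 <= thr <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {thr}")
        if abundance_mode not in ("mean", "max"):
            raise ValidationError(f"unknown abundance_mode {abundance_mode!r}")
        rel = self.relative_abundance().values
        if abundance_mode == "mean":
            abund = rel.mean(axis=1)
        else:
            abund = rel.max(axis=1)
        prevalence = (self.values > 0).mean(axis=1)
        kept = (abund >= min_mean_rel_abund) & (prevalence >= min_prevalence)
        report = pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                f"{abundance_mode}_rel_abund": abund,
                "prevalence": prevalence,
                "kept": kept,
            }
        ).set_index("feature_id")
        table = OtuTable(self.data.loc[kept], kind=self.kind, taxonomy=self.taxonomy)
        return table, report

    def aggregate_taxa(self, taxonomy: TaxonomyMap, rank: str) -> "OtuTable":
        """Sum features sharing a rank label; unassigned features collapse
        into an ``'unassigned'`` row so per-sample totals are conserved."""
        if rank not in AGGREGATION_RANKS:
            raise ValidationError(
                f"rank must be one of {AGGREGATION_RANKS}, got {rank!r}"
            )
        labels = [taxonomy.label(fid, rank) for fid in self.feature_ids]
        frame = self.data.groupby(pd.Index(labels, name=rank), sort=False).sum()
        # deterministic order: assigned labels alphabetically, unassigned last
        order = sorted(l for l in frame.index if l != UNASSIGNED)
        if UNASSIGNED in frame.index:
            order.append(UNASSIGNED)
        return OtuTable(frame.loc[order], kind=self.kind, taxonomy=None)


# ---------------------------------------------------------------------------
# module-level operation aliases


def rarefy(table: OtuTable, depth: int, seed=None, drop_low: bool = False) -> OtuTable:
    return table.rarefy(depth, seed=seed, drop_low=drop_low)


def to_relative_abundance(table: OtuTable) -> OtuTable:
    return table.relative_abundance()


def filter_features(table, min_mean_rel_abund, min_prevalence, abundance_mode="mean"):
    return table.filter_features(min_mean_rel_abund, min_prevalence, abundance_mode)


def aggregate_taxa(table: OtuTable, taxonomy: TaxonomyMap, rank: str) -> OtuTable:
    return table.aggregate_taxa(taxonomy, rank)


def fb_ratio(table: OtuTable, taxonomy: TaxonomyMap) -> pd.Series:
    """Per-sample Firmicutes/Bacteroidetes abundance ratio.

    Samples with zero Bacteroidetes abundance get NaN (reported missing,
    never infinity).
    """
    phyla = table.aggregate_taxa(taxonomy, "phylum")
    def _row(name):
        if name in phyla.data.index:
            return phyla.data.loc[name].to_numpy(dtype=float)
        return np.zeros(table.n_samples)
    firm = _row("Firmicutes")
    bact = _row("Bacteroidetes")
    ratio = np.full(table.n_samples, np.nan)
    ok = bact > 0
    ratio[ok] = firm[ok] / bact[ok]
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} samples have zero Bacteroidetes abundance; "
            "F/B ratio reported as missing",
            stacklevel=2,
        )
    return pd.Series(ratio, index=table.sample_ids, name="fb_ratio")


# ---------------------------------------------------------------------------
# feature-table I/O


def _parse_numeric(frame: pd.DataFrame, path) -> pd.DataFrame:
    out = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        for i, (rid, cell) in enumerate(zip(frame.index, frame[col])):
            text = cell.strip()
            if text == "":
                raise ParseError(f"{path}: empty cell at row {rid!r}, column {col!r}")
            try:
                out[i, j] = float(text)
            except ValueError:
                raise ParseError(
                    f"{path}: malformed numeric cell {cell!r} at row {rid!r}, "
                    f"column {col!r}"
                ) from None
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)


def read_feature_table(path, orientation: str = "features",
                       kind: str = "counts") -> OtuTable:
    """Read a TSV feature table.

    The first column holds ids (a leading ``#OTU ID`` header cell is the
    BIOM-TSV dialect); ``orientation`` declares whether rows are features or
    samples. A trailing ``taxonomy`` column is split off into the returned
    table's ``.taxonomy`` attribute. Empty cells and malformed numbers are
    hard errors naming the offending row and column.
    """
    if orientation not in ("features", "samples"):
        raise ValidationError("orientation must be 'features' or 'samples'")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "header")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected id column plus data columns")
    ids = raw.iloc[:, 0].astype(str).str.strip()
    _check_unique(ids, "row")
    body = raw.iloc[:, 1:]
    body.index = ids
    taxonomy = None
    if str(body.columns[-1]).strip().lower() == "taxonomy":
        if orientation != "features":
            raise ValidationError("taxonomy column requires features-in-rows")
        taxonomy = TaxonomyMap.from_strings(dict(zip(ids, body.iloc[:, -1])))
        body = body.iloc[:, :-1]
    _check_unique(body.columns, "column")
    frame = _parse_numeric(body, path)
    if orientation == "samples":
        frame = frame.T
    return OtuTable(frame, kind=kind, taxonomy=taxonomy)


def write_feature_table(table: OtuTable, path, id_header: str = "#OTU ID") -> None:
    """Write a TSV feature table, features in rows, BIOM-TSV style header."""
    vals = table.data
    if table.kind == "counts":
        rounded = np.rint(vals.to_numpy(float))
        if np.allclose(vals.to_numpy(float), rounded):
            vals = pd.DataFrame(rounded.astype(np.int64), index=vals.index,
                                columns=vals.columns)
    out = vals.copy()
    out.index.name = id_header
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# phenotypes


class PhenotypeTable:
    """Sample phenotypes: sex, batch, and the serum traits
    GLU/TCHOL/TG/HDL/LDL plus the derived indices LDL/HDL and AI.

    ``sex`` is required; a missing ``batch`` column defaults to a single
    level with a warning (the variance-explained stage adjusts for both).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = pd.DataFrame(frame).copy()
        if "sample_id" in frame.columns:
            frame = frame.set_index("sample_id")
        _check_unique(frame.index, "sample")
        if "sex" not in frame.columns:
            raise ValidationError("phenotype table requires a 'sex' column")
        if "batch" not in frame.columns:
            warnings.warn("no 'batch' column; assuming a single batch", stacklevel=2)
            frame["batch"] = "batch1"
        frame["sex"] = frame["sex"].astype(str)
        frame["batch"] = frame["batch"].astype(str)
        for trait in TRAIT_COLUMNS + DERIVED_TRAITS:
            if trait in frame.columns:
                frame[trait] = pd.to_numeric(frame[trait])
        self.data = frame

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    def trait(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise ValidationError(f"unknown trait {name!r}")
        return self.data[name]

    def traits_present(self) -> list[str]:
        return [t for t in TRAIT_COLUMNS + DERIVED_TRAITS if t in self.data.columns]

    def covariates(self, names=("sex", "batch")) -> pd.DataFrame:
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise ValidationError(f"missing covariate columns: {missing}")
        return self.data[list(names)]

    def derive_lipid_indices(self) -> "PhenotypeTable":
        """Add AI = (TCHOL - HDL)/HDL and LDL_HDL = LDL/HDL.

        Rows with HDL <= 0 get missing derived values with a warning.
        Original columns are unchanged.
        """
        frame = self.data.copy()
        for col in ("TCHOL", "HDL", "LDL"):
            if col not in frame.columns:
                raise ValidationError(f"lipid indices need column {col!r}")
        hdl = frame["HDL"].to_numpy(dtype=float)
        ok = hdl > 0
        if (~ok).any():
            warnings.warn(
                f"{int((~ok).sum())} samples have HDL <= 0; derived indices set "
                "to missing",
                stacklevel=2,
            )
        ai = np.full(len(frame), np.nan)
        ldl_hdl = np.full(len(frame), np.nan)
        tc = frame["TCHOL"].to_numpy(dtype=float)
        ldl = frame["LDL"].to_numpy(dtype=float)
        ai[ok] = (tc[ok] - hdl[ok]) / hdl[ok]
        ldl_hdl[ok] = ldl[ok] / hdl[ok]
        frame["LDL_HDL"] = ldl_hdl
        frame["AI"] = ai
        return PhenotypeTable(frame)

    def write(self, path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        sep = "," if str(path).endswith(".csv") else "\t"
        out.to_csv(path, sep=sep)


def read_phenotypes(path) -> PhenotypeTable:
    """Read a CSV/TSV phenotype file with header
    ``sample_id,sex,batch,GLU,TCHOL,TG,HDL,LDL`` (extra columns pass through)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep)
    if "sample_id" not in frame.columns:
        raise ParseError(f"{path}: phenotype file needs a 'sample_id' column")
    return PhenotypeTable(frame)


def derive_lipid_indices(pheno: PhenotypeTable) -> PhenotypeTable:
    return pheno.derive_lipid_indices()
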