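"""Readers, writers and the cohort data model.

All tabular inputs are UTF-8 tab-separated files; lines starting with ``#``
are comments.  Five tables feed the analysis: a miRNA expression matrix
(miRNAs x samples), a MAF-lite somatic mutation table, a clinical table,
gene-level HR-defect evidence tables, and a curated miRNA--DDR-gene edge
list.  :func:`assemble_cohort` aligns them on the intersection of their
sample universes.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MirgiError",
    "ValidationError",
    "SchemaError",
    "ParseError",
    "ExpressionMatrix",
    "MafTable",
    "CohortBundle",
    "NETWORK_PATHWAYS",
    "DEBULKING_VOCAB",
    "normalize_sample_id",
    "normalize_mirna_id",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_maf_lite",
    "read_clinical",
    "read_network_edges",
    "read_table",
    "write_table",
    "assemble_cohort",
]


class MirgiError(Exception):
    """Base class for package errors."""


class ValidationError(MirgiError):
    """An input violates a declared invariant."""


class SchemaError(MirgiError):
    """A table is missing mandatory columns."""


class ParseError(MirgiError):
    """A cell could not be coerced to its declared type."""


#: Vocabulary of DNA-repair pathway classes for network edges.
NETWORK_PATHWAYS = frozenset({"HR", "NHEJ", "MMR", "NER", "BER", "DDS", "other"})

#: Vocabulary of surgical-debulking categories.
DEBULKING_VOCAB = frozenset({"optimal", "suboptimal", "unknown"})

_NA_TOKENS = {"", "NA", "N/A", "NaN", "nan", "null", "NULL", "."}


def normalize_sample_id(sample_id: str, truncate_tcga: bool = True) -> str:
    """Canonicalise a sample identifier.

    Whitespace is trimmed and the identifier upper-cased.  TCGA-style
    barcodes are truncated (by default) to the participant+sample prefix
    ``TCGA-XX-YYYY-SS`` so that tables mixing barcode lengths still match.
    """
    s = str(sample_id).strip().upper()
    if truncate_tcga and s.startswith("TCGA-"):
        parts = s.split("-")
        if len(parts) >= 4:
            s = "-".join(parts[:3]) + "-" + parts[3][:2]
    return s


def normalize_mirna_id(mirna_id: str) -> str:
    """Canonicalise a miRNA identifier.

    Lower-cases, strips whitespace and any ``hsa-`` species prefix, and
    unifies the ``mir``/``miR`` capitalisation; a trailing ``*`` (minor
    strand) is preserved verbatim.
    """
    s = str(mirna_id).strip().lower()
    if s.startswith("hsa-"):
        s = s[4:]
    return s


def _resolve(path):
    return sys.stdin if str(path) == "-" else path


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        _resolve(path),
        sep="\t",
        comment="#",
        dtype=str,
        keep_default_na=False,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """miRNA-by-sample expression values.

    ``values`` is a DataFrame indexed by miRNA identifier with sample
    identifiers as columns.  Identifiers are unique; missing measurements
    are NaN, never zero.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        for name, ids in (("miRNA", idx), ("sample", cols)):
            dup = ids[ids.duplicated()]
            if len(dup):
                raise ValidationError(f"duplicated {name} identifier(s): {sorted(set(dup))}")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)].copy())


def read_expression_matrix(
    path,
    *,
    normalize_samples: bool = True,
    truncate_tcga: bool = True,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column miRNA ids, header samples).

    Raises :class:`ValidationError` on duplicated identifiers (naming the
    duplicate) and :class:`ParseError` on non-numeric cells (naming the
    row and column).  ``NA``-like tokens become missing values.
    """
    raw = _read_tsv(path, index_col=0)
    raw.index = [normalize_mirna_id(m) for m in raw.index]
    if normalize_samples:
        raw.columns = [normalize_sample_id(c, truncate_tcga) for c in raw.columns]
    numeric = raw.replace(list(_NA_TOKENS), np.nan).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~raw.isin(_NA_TOKENS)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric cell {raw.iat[r, c]!r} at miRNA {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}"
        )
    return ExpressionMatrix(numeric)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="mirna_id", na_rep="NA")


# ---------------------------------------------------------------------------
# MAF-lite mutations
# ---------------------------------------------------------------------------

#: Column-name aliases (lower-cased) for MAF-lite input, in priority order.
MAF_ALIASES: dict[str, tuple[str, ...]] = {
    "sample_id": ("tumor_sample_barcode", "sample", "sample_id"),
    "gene_symbol": ("hugo_symbol", "gene", "gene_symbol"),
    "chromosome": ("chromosome", "chrom", "chr"),
    "position": ("start_position", "position", "pos", "start"),
    "variant_class": ("variant_classification", "class", "variant_class"),
    "ref_allele": ("reference_allele", "ref", "ref_allele"),
    "alt_allele": ("tumor_seq_allele2", "alt", "alt_allele"),
}

_MAF_MANDATORY = ("sample_id", "gene_symbol", "chromosome", "position", "variant_class")


@dataclass
class MafTable:
    """Parsed somatic mutations plus a reject report.

    ``records`` holds one row per accepted mutation with canonical columns;
    ``rejects`` holds the raw rows that failed coercion, with a ``reason``
    column.  Rows are never silently dropped:
    ``len(records) + len(rejects)`` equals the input row count.
    """

    records: pd.DataFrame
    rejects: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)


def read_maf_lite(
    path,
    *,
    aliases: Mapping[str, Sequence[str]] | None = None,
    truncate_tcga: bool = True,
) -> MafTable:
    """Read a MAF-lite TSV into canonical mutation records."""
    alias_map = {k: tuple(a.lower() for a in v) for k, v in MAF_ALIASES.items()}
    if aliases:
        for k, v in aliases.items():
            alias_map[k] = tuple(a.lower() for a in v) + alias_map.get(k, ())
    raw = _read_tsv(path)
    lower = {c.lower(): c for c in raw.columns}
    colmap: dict[str, str] = {}
    for canon, names in alias_map.items():
        for name in names:
            if name in lower:
                colmap[canon] = lower[name]
                break
    missing = [c for c in _MAF_MANDATORY if c not in colmap]
    if missing:
        raise SchemaError(
            "MAF-lite input is missing mandatory column(s): "
            + "; ".join(f"{m} (aliases: {', '.join(alias_map[m])})" for m in missing)
        )

    out = pd.DataFrame(
        {canon: raw[col] for canon, col in colmap.items()},
        index=raw.index,
    )
    for optional in ("ref_allele", "alt_allele"):
        if optional not in out:
            out[optional] = ""
    reasons = pd.Series("", index=out.index, dtype=object)
    pos = pd.to_numeric(out["position"], errors="coerce")
    reasons[pos.isna()] = "position is not an integer"
    reasons[pos.notna() & (pos < 1)] = "position < 1"
    reasons[out["sample_id"].str.strip() == ""] = "empty sample_id"
    ok = reasons == ""
    records = out[ok].copy()
    records["position"] = pos[ok].astype(int)
    records["sample_id"] = [
        normalize_sample_id(s, truncate_tcga) for s in records["sample_id"]
    ]
    rejects = raw[~ok].copy()
    rejects["reason"] = reasons[~ok]
    return MafTable(records.reset_index(drop=True), rejects.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS: dict[str, tuple[str, ...]] = {
    "sample_id": ("sample_id", "sample", "bcr_patient_barcode"),
    "os_time": ("os_time", "os_years", "time"),
    "os_event": ("os_event", "event", "vital_status"),
    "pfs_time": ("pfs_time", "pfs_years"),
    "pfs_event": ("pfs_event",),
    "age": ("age", "age_at_diagnosis"),
    "figo_stage": ("figo_stage", "stage"),
    "grade": ("grade", "histological_grade"),
    "debulking": ("debulking", "residual_disease"),
    "platinum_sensitive": ("platinum_sensitive", "platinum_status"),
    "complete_response": ("complete_response", "cr"),
    "is_tumour": ("is_tumour", "is_tumor", "tumour"),
}

_TRUE_TOKENS = {"1", "true", "t", "yes", "y", "sensitive", "dead", "deceased"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n", "resistant", "alive", "living"}


def _coerce_bool(series: pd.Series) -> pd.Series:
    def conv(v):
        s = str(v).strip().lower()
        if s in _NA_TOKENS or s == "nan":
            return pd.NA
        if s in _TRUE_TOKENS:
            return True
        if s in _FALSE_TOKENS:
            return False
        return pd.NA

    return series.map(conv).astype("boolean")


def read_clinical(
    path,
    *,
    column_map: Mapping[str, str] | None = None,
    truncate_tcga: bool = True,
) -> pd.DataFrame:
    """Read a clinical TSV into per-sample outcome and covariate records.

    Survival times are in years.  Categorical vocabularies are matched
    case-insensitively; values outside a vocabulary are mapped to
    ``unknown`` and counted in the returned frame's
    ``attrs["n_unknown_category"]``.  A negative survival time raises
    :class:`ValidationError`.
    """
    raw = _read_tsv(path)
    lower = {c.lower(): c for c in raw.columns}
    colmap: dict[str, str] = {}
    for canon, names in CLINICAL_COLUMNS.items():
        if column_map and canon in column_map:
            colmap[canon] = column_map[canon]
            continue
        for name in names:
            if name in lower:
                colmap[canon] = lower[name]
                break
    for mandatory in ("sample_id", "os_time", "os_event"):
        if mandatory not in colmap:
            raise SchemaError(f"clinical table is missing mandatory column {mandatory!r}")

    out = pd.DataFrame(index=raw.index)
    out["sample_id"] = [normalize_sample_id(s, truncate_tcga) for s in raw[colmap["sample_id"]]]
    n_unknown = 0
    for tcol in ("os_time", "pfs_time", "age"):
        if tcol in colmap:
            out[tcol] = pd.to_numeric(raw[colmap[tcol]].replace(list(_NA_TOKENS), np.nan), errors="coerce")
    for neg_col in ("os_time", "pfs_time"):
        if neg_col in out and (out[neg_col] < 0).any():
            bad = out.loc[out[neg_col] < 0, "sample_id"].iloc[0]
            raise ValidationError(f"negative {neg_col} for sample {bad}")
    for bcol in ("os_event", "pfs_event", "platinum_sensitive", "complete_response", "is_tumour"):
        if bcol in colmap:
            out[bcol] = _coerce_bool(raw[colmap[bcol]])
    for ocol in ("figo_stage", "grade"):
        if ocol in colmap:
            out[ocol] = pd.to_numeric(
                raw[colmap[ocol]].astype(str).str.strip().str.upper()
                .str.replace("STAGE", "", regex=False)
                .str.replace("G", "", regex=False)
                .replace({"IV": "4", "III": "3", "II": "2", "I": "1"})
                .replace(list(_NA_TOKENS), np.nan),
                errors="coerce",
            )
    if "debulking" in colmap:
        deb = raw[colmap["debulking"]].astype(str).str.strip().str.lower()
        known = deb.isin(DEBULKING_VOCAB) | deb.isin(_NA_TOKENS)
        n_unknown += int((~known).sum())
        deb = deb.where(deb.isin(DEBULKING_VOCAB), "unknown")
        out["debulking"] = deb
    if "is_tumour" not in out:
        out["is_tumour"] = True
    out["is_tumour"] = out["is_tumour"].fillna(True)
    if n_unknown:
        warnings.warn(f"{n_unknown} categorical value(s) outside vocabulary mapped to 'unknown'")
    out.attrs["n_unknown_category"] = n_unknown
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Network edge list
# ---------------------------------------------------------------------------


def read_network_edges(path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a miRNA--target edge list TSV (columns mirna, gene, pathway).

    Edges are deduplicated on (mirna, gene); returns the edge frame and a
    summary ``{"n_edges", "n_mirnas", "n_genes"}``.  A pathway label
    outside the vocabulary raises :class:`ValidationError`.
    """
    raw = _read_tsv(path)
    lower = {c.lower(): c for c in raw.columns}
    cols = {}
    for canon, names in (("mirna_id", ("mirna", "mirna_id")),
                         ("target_gene", ("gene", "target", "target_gene")),
                         ("pathway_class", ("pathway", "pathway_class"))):
        for name in names:
            if name in lower:
                cols[canon] = lower[name]
                break
        else:
            raise SchemaError(f"network edge list is missing column {canon!r}")
    edges = pd.DataFrame(
        {
            "mirna_id": [normalize_mirna_id(m) for m in raw[cols["mirna_id"]]],
            "target_gene": raw[cols["target_gene"]].str.strip().str.upper(),
            "pathway_class": raw[cols["pathway_class"]].str.strip(),
        }
    )
    if "evidence" in lower:
        edges["evidence"] = raw[lower["evidence"]]
    bad = sorted(set(edges["pathway_class"]) - NETWORK_PATHWAYS)
    if bad:
        raise ValidationError(
            f"pathway label(s) outside vocabulary {sorted(NETWORK_PATHWAYS)}: {bad}"
        )
    edges = edges.drop_duplicates(subset=["mirna_id", "target_gene"]).reset_index(drop=True)
    summary = {
        "n_edges": len(edges),
        "n_mirnas": edges["mirna_id"].nunique(),
        "n_genes": edges["target_gene"].nunique(),
    }
    return edges, summary


# ---------------------------------------------------------------------------
# Generic helpers and cohort assembly
# ---------------------------------------------------------------------------


def packaged_network_path() -> str:
    """Path of the packaged stand-in DDR network edge list.

    A synthetic fixture: nine literature-documented miRNA-target edges
    padded with deterministic synthetic filler to the published network
    shape (142 edges, 75 miRNAs, 55 DDR genes).
    """
    from importlib.resources import files

    return str(files("mirgi").joinpath("data/ddr_network_synthetic.tsv"))


def packaged_signature_path() -> str:
    """Path of the packaged 10-miRNA signature file (6 positive, 4 negative)."""
    from importlib.resources import files

    return str(files("mirgi").joinpath("data/signature10.tsv"))


def read_table(path) -> pd.DataFrame:
    """Read a generic TSV with type inference (comments ignored)."""
    return pd.read_csv(_resolve(path), sep="\t", comment="#")


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class CohortBundle:
    """Aligned analysis inputs on a shared sample universe.

    The universe is the intersection of sample identifiers present in the
    expression, mutation and clinical tables, ordered lexicographically.
    Per-source dropped-sample counts are recorded in ``dropped``.
    """

    expression: ExpressionMatrix
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    defects: pd.DataFrame | None = None
    network: pd.DataFrame | None = None
    sample_ids: list[str] = field(default_factory=list)
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def assemble_cohort(
    expression: ExpressionMatrix,
    mutations: pd.DataFrame | MafTable,
    clinical: pd.DataFrame,
    defects: pd.DataFrame | None = None,
    network: pd.DataFrame | None = None,
) -> CohortBundle:
    """Align inputs on the intersection of their sample universes.

    Raises :class:`ValidationError` if the intersection is empty.  Sample
    ordering in the bundle is lexicographic, so assembly is invariant to
    input row order.
    """
    if isinstance(mutations, MafTable):
        mutations = mutations.records
    expr_samples = set(expression.sample_ids)
    mut_samples = set(mutations["sample_id"])
    clin_samples = set(clinical["sample_id"])
    universe = sorted(expr_samples & mut_samples & clin_samples)
    if not universe:
        raise ValidationError("empty sample universe: expression, mutations and clinical share no sample")
    dropped = {
        "expression": len(expr_samples) - len(universe),
        "mutations": len(mut_samples) - len(universe),
        "clinical": len(clin_samples) - len(universe),
    }
    uset = set(universe)
    clin = clinical[clinical["sample_id"].isin(uset)]
    clin = clin.sort_values("sample_id").reset_index(drop=True)
    muts = mutations[mutations["sample_id"].isin(uset)]
    muts = muts.sort_values(list(muts.columns)).reset_index(drop=True)
    dft = None
    if defects is not None:
        dft = defects[defects["sample_id"].isin(uset)].sort_values("sample_id").reset_index(drop=True)
    return CohortBundle(
        expression=expression.subset_samples(universe),
        mutations=muts,
        clinical=clin,
        defects=dft,
        network=network,
        sample_ids=universe,
        dropped=dropped,
    )
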