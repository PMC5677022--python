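"""Genome-instability index and HR-deficiency evidence.

The per-sample somatic mutation count is used as the genome-instability
index: ovarian tumours with deficient homologous recombination accumulate
more somatic mutations, so burden stratifies repair capacity.  This module
also derives the per-sample defect flags (BRCA1/2, EMSY, PTEN, core-HR)
and implements the two-feature 2-means consensus caller for epigenetic
silencing (hyper-methylated AND down-expressed).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import MafTable, ValidationError
from .stats import MannWhitneyResult, mann_whitney

__all__ = [
    "CORE_HR_GENES",
    "CN_VOCAB",
    "mutation_counts",
    "compare_defect_instability",
    "call_epigenetic_silencing",
    "annotate_defects",
]

#: Default core homologous-recombination gene set (configurable): the
#: canonical HR effectors plus the Fanconi anaemia genes.
CORE_HR_GENES = frozenset(
    {
        "BRCA1", "BRCA2", "RAD51", "RAD51C", "RAD51D", "BRIP1", "PALB2",
        "ATM", "ATR", "CHEK1", "CHEK2",
        "FANCA", "FANCB", "FANCC", "FANCD2", "FANCE", "FANCF", "FANCG",
        "FANCI", "FANCL", "FANCM",
    }
)

#: Gene-level copy-number call vocabulary.
CN_VOCAB = frozenset({"amp", "neutral", "homodel"})


def mutation_counts(
    mutations: pd.DataFrame | MafTable,
    samples: Sequence[str],
    *,
    exclude_classes: Iterable[str] = (),
) -> pd.Series:
    """Per-sample somatic mutation count over a sample universe.

    Every sample in ``samples`` receives a count (0 if absent from the
    mutation table).  Duplicate records — same sample, chromosome,
    position and alternate allele — are counted once.  ``exclude_classes``
    drops variant classes (case-insensitive), e.g. ``{"silent"}`` for a
    non-silent-only count; the default counts all somatic records.
    """
    if isinstance(mutations, MafTable):
        mutations = mutations.records
    samples = list(samples)
    if not samples:
        raise ValidationError("sample universe is empty")
    recs = mutations
    if exclude_classes:
        excl = {c.lower() for c in exclude_classes}
        recs = recs[~recs["variant_class"].str.lower().isin(excl)]
    dedup_cols = ["sample_id", "chromosome", "position", "alt_allele"]
    recs = recs.drop_duplicates(subset=[c for c in dedup_cols if c in recs.columns])
    counts = recs.groupby("sample_id").size()
    out = counts.reindex(samples, fill_value=0).astype(int)
    out.name = "mutation_count"
    out.index.name = "sample_id"
    return out


def compare_defect_instability(index: pd.Series, flags: pd.Series) -> MannWhitneyResult:
    """Mann-Whitney comparison of the instability index between flagged
    (e.g. BRCA-deficient) and unflagged samples.

    The first group of the result is the flagged one; group medians are
    carried on the result.  Raises if either group is empty.
    """
    flags = flags.reindex(index.index)
    if flags.isna().any():
        raise ValidationError("defect flags missing for some samples in the index")
    flagged = index[flags.astype(bool)]
    unflagged = index[~flags.astype(bool)]
    if len(flagged) == 0 or len(unflagged) == 0:
        raise ValidationError("both flagged and unflagged groups must be non-empty")
    return mann_whitney(flagged.to_numpy(), unflagged.to_numpy())


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def call_epigenetic_silencing(
    methylation: pd.Series,
    expression: pd.Series,
    *,
    restarts: int = 25,
    seed: int | None = None,
) -> pd.DataFrame:
    """Call epigenetically silenced samples for one gene.

    Both features are z-scored and clustered by 2-means with ``restarts``
    random initialisations; the consensus assignment is the majority vote
    over restarts.  A cluster is labelled silenced only when it has both
    the higher mean methylation and the lower mean expression; when no
    cluster satisfies that conjunction, no sample is called silenced.
    Constant input vectors yield all-false calls with a warning.
    """
    from sklearn.cluster import KMeans

    if not methylation.index.equals(expression.index):
        expression = expression.reindex(methylation.index)
    if expression.isna().any() or methylation.isna().any():
        raise ValidationError("silencing caller requires complete methylation and expression vectors")
    n = len(methylation)
    if n < 4:
        raise ValidationError("silencing caller requires at least 4 samples")
    meth = methylation.to_numpy(dtype=float)
    expr = expression.to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "sample_id": methylation.index,
            "silenced": False,
            "methylation_z": _zscore(meth),
            "expression_z": _zscore(expr),
        }
    )
    if meth.std(ddof=0) == 0 or expr.std(ddof=0) == 0:
        warnings.warn("constant feature vector: no silencing calls made")
        return out

    X = np.column_stack([out["methylation_z"], out["expression_z"]])
    rng = np.random.default_rng(seed)
    votes = np.zeros(n, dtype=int)
    for _ in range(restarts):
        km = KMeans(n_clusters=2, n_init=1, random_state=int(rng.integers(0, 2**31 - 1)))
        labels = km.fit_predict(X)
        silenced_cluster = None
        for c in (0, 1):
            other = 1 - c
            in_c = labels == c
            if not in_c.any() or in_c.all():
                continue
            if (
                meth[in_c].mean() > meth[~in_c].mean()
                and expr[in_c].mean() < expr[~in_c].mean()
            ):
                silenced_cluster = c
                break
        if silenced_cluster is not None:
            votes += (labels == silenced_cluster).astype(int)
    out["silenced"] = votes > restarts / 2
    # Enforce the invariant silenced => hyper-methylated and down-expressed.
    out.loc[(out["methylation_z"] <= 0) | (out["expression_z"] >= 0), "silenced"] = False
    return out


def annotate_defects(
    gene_mutations: pd.DataFrame,
    copy_number_calls: pd.DataFrame,
    silencing: pd.DataFrame | None = None,
    core_hr_genes: Iterable[str] = CORE_HR_GENES,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build the per-sample HR-deficiency evidence table.

    ``gene_mutations``: long frame (sample_id, gene, flag) of somatic
    mutation indicators.  ``copy_number_calls``: long frame (sample_id,
    gene, call) with call in {amp, neutral, homodel}.  ``silencing``:
    BRCA1 silencing calls (sample_id, silenced), optional.

    Derived flags:
    ``brca_defect`` = BRCA1 mutated or methylated, or BRCA2 mutated;
    ``hr_defect``   = brca_defect or EMSY amplified or PTEN homozygously
    deleted or any core-HR gene altered (mutated or deleted).
    """
    core = {g.upper() for g in core_hr_genes}
    muts = gene_mutations.copy()
    muts["gene"] = muts["gene"].str.upper()
    muts["flag"] = muts["flag"].astype(bool)
    cn = copy_number_calls.copy()
    cn["gene"] = cn["gene"].str.upper()
    bad = sorted(set(cn["call"]) - CN_VOCAB)
    if bad:
        raise ValidationError(f"copy-number call(s) outside vocabulary {sorted(CN_VOCAB)}: {bad}")

    if samples is None:
        samples = sorted(set(muts["sample_id"]) | set(cn["sample_id"]))
    samples = list(samples)
    table = pd.DataFrame({"sample_id": samples})

    def mutated(gene: str) -> pd.Series:
        hit = muts[(muts["gene"] == gene) & muts["flag"]]["sample_id"]
        return table["sample_id"].isin(set(hit))

    def cn_is(gene: str, call: str) -> pd.Series:
        hit = cn[(cn["gene"] == gene) & (cn["call"] == call)]["sample_id"]
        return table["sample_id"].isin(set(hit))

    table["brca1_mutated"] = mutated("BRCA1")
    table["brca2_mutated"] = mutated("BRCA2")
    if silencing is not None and len(silencing):
        sil = set(silencing.loc[silencing["silenced"].astype(bool), "sample_id"])
        table["brca1_methylated"] = table["sample_id"].isin(sil)
    else:
        table["brca1_methylated"] = False
    table["emsy_amplified"] = cn_is("EMSY", "amp")
    table["pten_deleted"] = cn_is("PTEN", "homodel")

    core_mut = muts[muts["gene"].isin(core) & muts["flag"]]["sample_id"]
    core_del = cn[cn["gene"].isin(core) & (cn["call"] == "homodel")]["sample_id"]
    table["core_hr_altered"] = table["sample_id"].isin(set(core_mut) | set(core_del))

    table["brca_defect"] = (
        table["brca1_mutated"] | table["brca1_methylated"] | table["brca2_mutated"]
    )
    table["hr_defect"] = (
        table["brca_defect"]
        | table["emsy_amplified"]
        | table["pten_deleted"]
        | table["core_hr_altered"]
    )
    return table
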