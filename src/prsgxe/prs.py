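"""Weighted polygenic risk scores (PRS) and quartile categories.

A PRS is the weighted sum of risk-allele dosages over a fixed panel of
variants, the weights being log-odds ratios taken from prior GWAS.  The
score is used downstream as a four-level categorical variable (quartiles,
lowest quartile as referent), so the functions here cover three steps:
aligning an external weight table to the allele a genotype file actually
counts, computing the score, and assigning quartile categories from a
chosen basis population (by default the controls).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

WEIGHT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "weight"]

_AMBIGUOUS_PAIRS = frozenset({frozenset({"A", "T"}), frozenset({"C", "G"})})


class AlignmentError(ValueError):
    """A weight-table variant could not be matched to the genotype panel."""


class QuartileError(ValueError):
    """Quartile cut points are undefined (degenerate PRS distribution)."""


def validate_weight_table(weights: pd.DataFrame) -> pd.DataFrame:
    """Check a weight table for the invariants the score relies on.

    Requires the columns ``variant_id, chrom, pos, effect_allele,
    other_allele, weight``; unique variant ids; effect allele distinct from
    the other allele; finite weights.  Returns the validated frame.
    """
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise ValueError(f"weight table missing columns: {missing}")
    if weights["variant_id"].duplicated().any():
        dups = weights.loc[weights["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"duplicate variant ids in weight table: {dups[:5]}")
    same = weights["effect_allele"] == weights["other_allele"]
    if same.any():
        raise ValueError(
            "effect_allele equals other_allele for: "
            f"{weights.loc[same, 'variant_id'].tolist()[:5]}"
        )
    if not np.isfinite(weights["weight"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite weights in weight table")
    return weights


def is_strand_ambiguous(effect_allele: str, other_allele: str) -> bool:
    """A/T and C/G pairs cannot be strand-resolved from alleles alone."""
    return frozenset({effect_allele.upper(), other_allele.upper()}) in _AMBIGUOUS_PAIRS


@dataclass
class AlignedWeights:
    """Weight table expressed on the genotype file's counted allele.

    When the genotype file counts the weight table's *other* allele, the
    dosage reflection g -> 2 - g is absorbed by flipping the weight sign and
    adding ``2 * weight`` to :attr:`offset`, so that
    ``PRS = offset + sum_i w_i * g_i`` is identical to the score computed on
    the original encoding.
    """

    weights: pd.DataFrame
    offset: float
    n_flipped: int
    ambiguous_ids: list[str]


def align_weights(
    weights: pd.DataFrame,
    variant_meta: pd.DataFrame,
    drop_ambiguous: bool = False,
) -> AlignedWeights:
    """Align a weight table to the allele counted by the genotype source.

    Parameters
    ----------
    weights
        Validated weight table (see :func:`validate_weight_table`).
    variant_meta
        Per-variant metadata from the genotype source with columns
        ``variant_id, chrom, pos, counted_allele, other_allele``.
    drop_ambiguous
        Drop strand-ambiguous (A/T, C/G) variants instead of keeping them
        with a warning.

    Raises
    ------
    AlignmentError
        If any weight-table variant matches neither by id nor by
        coordinates + alleles, or if its alleles disagree with the genotype
        metadata.
    """
    validate_weight_table(weights)
    meta = variant_meta.set_index("variant_id")
    by_coord = variant_meta.set_index(["chrom", "pos"])

    rows = []
    offset = 0.0
    n_flipped = 0
    ambiguous: list[str] = []
    unmatched: list[str] = []
    for rec in weights.itertuples(index=False):
        if rec.variant_id in meta.index:
            m = meta.loc[rec.variant_id]
        elif (rec.chrom, rec.pos) in by_coord.index:
            m = by_coord.loc[(rec.chrom, rec.pos)]
        else:
            unmatched.append(rec.variant_id)
            continue
        counted, other = str(m["counted_allele"]), str(m["other_allele"])
        if is_strand_ambiguous(rec.effect_allele, rec.other_allele):
            ambiguous.append(rec.variant_id)
            if drop_ambiguous:
                continue
        row = dict(zip(WEIGHT_COLUMNS, (rec.variant_id, rec.chrom, rec.pos,
                                        rec.effect_allele, rec.other_allele, rec.weight)))
        if counted == rec.effect_allele and other == rec.other_allele:
            pass
        elif counted == rec.other_allele and other == rec.effect_allele:
            # genotype counts the non-effect allele: g_eff = 2 - g_counted
            row["weight"] = -rec.weight
            offset += 2.0 * rec.weight
            n_flipped += 1
        else:
            raise AlignmentError(
                f"allele mismatch for {rec.variant_id}: weight table "
                f"{rec.effect_allele}/{rec.other_allele} vs genotype {counted}/{other}"
            )
        rows.append(row)
    if unmatched:
        raise AlignmentError(f"variants not found in genotype panel: {unmatched}")
    if ambiguous and not drop_ambiguous:
        warnings.warn(
            f"{len(ambiguous)} strand-ambiguous (A/T or C/G) variants kept as-is: "
            f"{ambiguous[:5]}",
            stacklevel=2,
        )
    aligned = pd.DataFrame(rows, columns=WEIGHT_COLUMNS)
    return AlignedWeights(weights=aligned, offset=offset,
                          n_flipped=n_flipped, ambiguous_ids=ambiguous)


def compute_prs(
    genotypes: pd.DataFrame,
    weights: pd.DataFrame | AlignedWeights,
    offset: float = 0.0,
) -> pd.Series:
    """Compute ``prs_j = offset + sum_i w_i g_ij`` for every subject.

    ``genotypes`` is a subjects x variants frame of effect-allele dosages in
    [0, 2]; ``weights`` a weight table (or :class:`AlignedWeights`, whose
    own offset is then used) covering exactly the genotyped variants.
    """
    if isinstance(weights, AlignedWeights):
        offset = weights.offset
        weights = weights.weights
    w = weights.set_index("variant_id")["weight"]
    missing = w.index.difference(genotypes.columns)
    if len(missing):
        raise ValueError(f"genotypes lack weighted variants: {list(missing)[:5]}")
    dosages = genotypes[w.index].to_numpy(dtype=float)
    if np.isnan(dosages).any():
        raise ValueError("missing dosages; impute or drop at load time")
    prs = dosages @ w.to_numpy() + offset
    return pd.Series(prs, index=genotypes.index, name="prs")


def quartile_cutpoints(prs: pd.Series, basis_mask: pd.Series | np.ndarray | None = None) -> np.ndarray:
    """25th/50th/75th percentiles of the basis group's PRS.

    Percentile rule: linear interpolation between order statistics (the
    numpy default), so for basis values 1..8 the cut points are
    2.75 / 4.5 / 6.25.
    """
    values = prs if basis_mask is None else prs[np.asarray(basis_mask, dtype=bool)]
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise QuartileError(f"need >= 8 subjects in the quartile basis, got {values.size}")
    if np.ptp(values) == 0:
        raise QuartileError("PRS values all tied; quartiles undefined")
    return np.quantile(values, [0.25, 0.5, 0.75], method="linear")


def assign_quartiles(
    prs: pd.Series,
    case_status: pd.Series | None = None,
    basis: str = "controls",
) -> pd.Series:
    """Assign quartile categories 1-4 from the basis group's cut points.

    Categories are the half-open intervals (-inf, q25], (q25, q50],
    (q50, q75], (q75, inf); every subject is categorized, including
    subjects outside the basis group whose PRS falls below/above the basis
    range.  ``basis`` is ``"controls"`` (default; requires ``case_status``)
    or ``"all"``.
    """
    if basis == "controls":
        if case_status is None:
            raise ValueError("basis='controls' requires case_status")
        mask = np.asarray(case_status) == 0
    elif basis == "all":
        mask = None
    else:
        raise ValueError(f"unknown quartile basis {basis!r}; use 'controls' or 'all'")
    cuts = quartile_cutpoints(prs, mask)
    # searchsorted with side='left' realises the half-open (lo, hi] intervals
    q = np.searchsorted(cuts, prs.to_numpy(dtype=float), side="left") + 1
    return pd.Series(q, index=prs.index, name="prs_q")
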