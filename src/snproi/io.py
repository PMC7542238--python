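"""Delimited-text I/O for genotype, phenotype, annotation, weight and report tables.

Genotypes are additively coded minor-allele counts: 0 = wild-type homozygote,
1 = heterozygote, 2 = mutant homozygote. Phenotypes are continuous imaging-derived
ROI summaries (volumes, thicknesses, densities). Files are UTF-8, tab- or
comma-delimited (auto-detected from the header line), with a header row of
SNP/ROI ids and a first column of sample ids.

Sample alignment between a genotype and a phenotype table is always an explicit
join on sample id, never positional — silent row misalignment is the classic
imaging-genetics bug this module is designed to prevent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("snproi")

MISSING_CODE = -1
GENOTYPE_ALPHABET = frozenset({0, 1, 2})


class FormatError(ValueError):
    """Malformed file structure (wrong row length, bad header)."""


class ValidationError(ValueError):
    """Structurally valid file with out-of-contract content."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive genotype codes with SNP metadata.

    values[i, j] is the minor-allele count of sample ``sample_ids[i]`` at SNP
    ``snp_ids[j]``; every entry lies in {0, 1, 2} (or the missing code -1
    before imputation).
    """

    values: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    gene_of: dict[str, str] | None = None
    position: dict[str, tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, p = self.values.shape
        if len(self.snp_ids) != p:
            raise ValidationError(f"{len(self.snp_ids)} SNP ids for {p} columns")
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.snp_ids)) != p:
            raise ValidationError("duplicate SNP ids")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def p_snps(self) -> int:
        return self.values.shape[1]

    def subset_snps(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        """Return a copy restricted to SNP columns ``idx`` (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        ids = [self.snp_ids[j] for j in idx]
        gene = {s: self.gene_of[s] for s in ids if s in self.gene_of} if self.gene_of else None
        pos = {s: self.position[s] for s in ids if s in self.position} if self.position else None
        return GenotypeMatrix(self.values[:, idx].copy(), ids, list(self.sample_ids), gene, pos)

    def subset_samples(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            self.values[idx].copy(), list(self.snp_ids),
            [self.sample_ids[i] for i in idx], self.gene_of, self.position,
        )


@dataclass
class PhenotypeMatrix:
    """Samples x ROIs continuous imaging phenotypes."""

    values: np.ndarray
    roi_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, q = self.values.shape
        if len(self.roi_ids) != q:
            raise ValidationError(f"{len(self.roi_ids)} ROI ids for {q} columns")
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.roi_ids)) != q or len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate ids")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite phenotype at sample {self.sample_ids[i]!r}, ROI {self.roi_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def q_rois(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, idx: np.ndarray | list[int]) -> "PhenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return PhenotypeMatrix(
            self.values[idx].copy(), list(self.roi_ids), [self.sample_ids[i] for i in idx]
        )


METRIC_NAMES = ("MAE", "RMSE", "MeAE", "MAPE", "R2", "RMSPE")


@dataclass
class MetricsReport:
    """Six regression error measures per ROI plus their unweighted mean."""

    per_roi: dict[str, dict[str, float]]
    aggregate: dict[str, float]
    n_features_used: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = {roi: vals for roi, vals in self.per_roi.items()}
        rows["aggregate"] = self.aggregate
        return pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]


def _detect_sep(path: str) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path: str) -> pd.DataFrame:
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                         keep_default_na=False, na_values=[])
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    # pandas pads short rows with NaN only when dtype coercion fails; enforce rectangularity
    ncols = df.shape[1]
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 or not line.strip():
                continue
            nfields = line.rstrip("\n").count(sep) + 1
            if nfields != ncols + 1:
                raise FormatError(
                    f"{path}: line {lineno} has {nfields} fields, expected {ncols + 1}"
                )
    return df


def read_genotypes(path: str, missing_code: int = MISSING_CODE,
                   impute: bool = False) -> GenotypeMatrix:
    """Read an additive genotype table (header = SNP ids, first column = sample ids).

    Entries must be in {0, 1, 2} or ``missing_code``. With ``impute=True``
    missing entries are replaced by the per-SNP mode of the observed codes
    (ties broken toward the smaller code); the count imputed is logged.
    """
    df = _read_table(path)
    snp_ids = [str(c) for c in df.columns]
    sample_ids = [str(i) for i in df.index]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric genotype entry ({exc})") from exc
    if not np.all(values == np.round(values)):
        i, j = np.argwhere(values != np.round(values))[0]
        raise ValidationError(
            f"non-integer genotype {values[i, j]} at SNP {snp_ids[j]!r}, sample {sample_ids[i]!r}"
        )
    values = values.astype(np.int64)
    bad = ~(np.isin(values, list(GENOTYPE_ALPHABET)) | (values == missing_code))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"genotype {values[i, j]} not in {{0,1,2,{missing_code}}} "
            f"at SNP {snp_ids[j]!r}, sample {sample_ids[i]!r}"
        )
    if impute:
        values = impute_mode(values, missing_code)
    elif (values == missing_code).any():
        logger.warning("genotype table %s contains %d missing entries (impute=False)",
                       path, int((values == missing_code).sum()))
    return GenotypeMatrix(values, snp_ids, sample_ids)


def impute_mode(values: np.ndarray, missing_code: int = MISSING_CODE) -> np.ndarray:
    """Replace missing genotype codes with the per-SNP mode of observed codes."""
    values = values.copy()
    n_imputed = 0
    for j in range(values.shape[1]):
        col = values[:, j]
        miss = col == missing_code
        if not miss.any():
            continue
        observed = col[~miss]
        if observed.size == 0:
            raise ValidationError(f"SNP column {j} is entirely missing; cannot impute")
        counts = np.bincount(observed, minlength=3)
        col[miss] = int(np.argmax(counts))  # argmax ties -> smaller code
        n_imputed += int(miss.sum())
    if n_imputed:
        logger.info("imputed %d missing genotypes by per-SNP mode", n_imputed)
    return values


def read_phenotypes(path: str) -> PhenotypeMatrix:
    """Read a continuous ROI phenotype table (header = ROI ids, first column = sample ids)."""
    df = _read_table(path)
    roi_ids = [str(c) for c in df.columns]
    sample_ids = [str(i) for i in df.index]
    arr = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                v = float(raw[i, j])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-numeric phenotype {raw[i, j]!r} at sample "
                    f"{sample_ids[i]!r}, ROI {roi_ids[j]!r}"
                ) from None
            arr[i, j] = v
    return PhenotypeMatrix(arr, roi_ids, sample_ids)  # __post_init__ rejects NaN/inf


def write_genotypes(g: GenotypeMatrix, path: str, sep: str = "\t") -> None:
    pd.DataFrame(g.values, index=g.sample_ids, columns=g.snp_ids).to_csv(path, sep=sep)


def write_phenotypes(ph: PhenotypeMatrix, path: str, sep: str = "\t") -> None:
    pd.DataFrame(ph.values, index=ph.sample_ids, columns=ph.roi_ids).to_csv(
        path, sep=sep, float_format="%.17g"
    )


def write_weights(W: np.ndarray, snp_ids: list[str], roi_ids: list[str],
                  path: str, sep: str = "\t") -> None:
    """Write a d x c weight matrix: rows = SNP ids, columns = ROI ids."""
    pd.DataFrame(W, index=snp_ids, columns=roi_ids).to_csv(path, sep=sep, float_format="%.17g")


def read_gene_map(path: str) -> dict[str, str]:
    """Two-column snp_id -> gene table."""
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: gene map needs two columns (snp_id, gene)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_gene_map(gene_of: dict[str, str], path: str, sep: str = "\t") -> None:
    pd.DataFrame({"snp_id": list(gene_of), "gene": list(gene_of.values())}).to_csv(
        path, sep=sep, index=False
    )


def write_metrics(report: MetricsReport, path: str, sep: str = "\t") -> None:
    report.to_frame().to_csv(path, sep=sep, float_format="%.10g")


def align_samples(g: GenotypeMatrix, ph: PhenotypeMatrix
                  ) -> tuple[GenotypeMatrix, PhenotypeMatrix]:
    """Restrict both matrices to the shared sample ids, co-ordered by id.

    The output order follows the genotype matrix's order restricted to the
    intersection. Idempotent; raises on an empty intersection.
    """
    ph_pos = {s: i for i, s in enumerate(ph.sample_ids)}
    g_keep = [i for i, s in enumerate(g.sample_ids) if s in ph_pos]
    if not g_keep:
        raise ValidationError("no shared sample ids between genotypes and phenotypes")
    ph_keep = [ph_pos[g.sample_ids[i]] for i in g_keep]
    dropped_g = g.n_samples - len(g_keep)
    dropped_ph = ph.n_samples - len(ph_keep)
    if dropped_g or dropped_ph:
        logger.info("align_samples: dropped %d genotype and %d phenotype samples",
                    dropped_g, dropped_ph)
    return g.subset_samples(g_keep), ph.subset_samples(ph_keep)
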