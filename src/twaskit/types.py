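"""Core data containers shared across the pipeline.

Conventions: genomic coordinates are 1-based inclusive everywhere inside the
package (BED input is converted at the boundary); dosages are unphased allele
counts in {0, 1, 2}; SNP weights and eQTL effects are stored on the
standardized-genotype scale unless a function says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SNPMap",
    "GenotypePanel",
    "LDMatrix",
    "TranscriptomeAnnotation",
    "ExpressionSet",
    "GWASSummary",
    "SimTruth",
    "WeightModel",
    "ModelDB",
    "AssociationRecord",
    "EffectiveSampleReport",
    "FeatureCorrelation",
    "FineMapResult",
    "QTLRecord",
    "ColocResult",
    "GWASLocus",
    "MediationEstimate",
]


@dataclass
class SNPMap:
    """Ordered table of SNP coordinates and alleles.

    Positions must be strictly increasing within each chromosome and
    snp_ids unique; validated on construction.
    """

    table: pd.DataFrame  # columns: snp_id, chrom, pos, allele_ref, allele_alt

    REQUIRED = ("snp_id", "chrom", "pos", "allele_ref", "allele_alt")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"SNPMap missing columns: {missing}")
        if self.table["snp_id"].duplicated().any():
            raise ValueError("SNPMap snp_ids must be unique")
        for _, grp in self.table.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing within chromosome")
        self.table = self.table.reset_index(drop=True)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, mask_or_ids) -> "SNPMap":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            tab = self.table.loc[mask_or_ids]
        else:
            keep = set(mask_or_ids)
            tab = self.table[self.table["snp_id"].isin(keep)]
        return SNPMap(tab.reset_index(drop=True))


@dataclass
class GenotypePanel:
    """Reference panel of unphased dosages (individuals x SNPs, values 0/1/2)."""

    dosages: np.ndarray
    snp_map: SNPMap
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if self.dosages.shape[1] != len(self.snp_map):
            raise ValueError("dosage columns do not match SNP map length")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")
        if self.sample_ids is None:
            self.sample_ids = [f"ind{i}" for i in range(self.dosages.shape[0])]

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        f = self.dosages.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def subset(self, mask: np.ndarray) -> "GenotypePanel":
        """Restrict to SNP columns where ``mask`` is True."""
        return GenotypePanel(self.dosages[:, mask], self.snp_map.subset(mask), self.sample_ids)

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages (mean 0, variance 1)."""
        X = self.dosages
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("cannot standardize monomorphic SNP columns")
        return (X - mu) / sd


@dataclass
class LDMatrix:
    """SNP-SNP Pearson correlation matrix with its SNP ordering."""

    snp_ids: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise ValueError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")
        w = np.linalg.eigvalsh((self.r + self.r.T) / 2.0)
        if w.min() < -1e-6:
            raise ValueError("LD matrix not positive semidefinite")

    def subset(self, snp_ids) -> "LDMatrix":
        index = {s: i for i, s in enumerate(self.snp_ids)}
        idx = np.array([index[s] for s in snp_ids])
        return LDMatrix(np.asarray(snp_ids), self.r[np.ix_(idx, idx)])


@dataclass
class TranscriptomeAnnotation:
    """Gene and transcript coordinates.

    genes: gene_id, chrom, strand, gene_start, gene_end, tss (1-based inclusive)
    transcripts: transcript_id, gene_id, tss
    """

    genes: pd.DataFrame
    transcripts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.transcripts["transcript_id"].duplicated().any():
            raise ValueError("transcript_ids must be unique")
        known = set(self.genes["gene_id"])
        orphans = set(self.transcripts["gene_id"]) - known
        if orphans:
            raise ValueError(f"transcripts reference unknown genes: {sorted(orphans)[:5]}")
        self.genes = self.genes.reset_index(drop=True)
        self.transcripts = self.transcripts.reset_index(drop=True)

    def transcripts_of(self, gene_id: str) -> list[str]:
        sub = self.transcripts[self.transcripts["gene_id"] == gene_id]
        return list(sub["transcript_id"])

    def gene_of(self, transcript_id: str) -> str:
        sub = self.transcripts[self.transcripts["transcript_id"] == transcript_id]
        if len(sub) != 1:
            raise KeyError(transcript_id)
        return sub["gene_id"].iloc[0]

    def gene_row(self, gene_id: str) -> pd.Series:
        sub = self.genes[self.genes["gene_id"] == gene_id]
        if len(sub) != 1:
            raise KeyError(gene_id)
        return sub.iloc[0]


@dataclass
class ExpressionSet:
    """Normalized expression matrix (individuals x features) plus covariates."""

    values: np.ndarray
    feature_ids: list[str]
    level: str  # "gene" or "isoform"
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_ids):
            raise ValueError("values shape does not match feature_ids")
        if np.isnan(self.values).any():
            raise ValueError("expression values must not contain NaN")
        if self.level not in ("gene", "isoform"):
            raise ValueError("level must be 'gene' or 'isoform'")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.feature_ids.index(feature_id)]


@dataclass
class GWASSummary:
    """Per-SNP GWAS summary statistics (z = beta/se)."""

    table: pd.DataFrame  # snp_id, chrom, pos, allele_ref, allele_alt, beta, se, z, n

    def __post_init__(self) -> None:
        t = self.table
        if "z" not in t.columns:
            t = t.assign(z=t["beta"] / t["se"])
        elif {"beta", "se"} <= set(t.columns):
            both = t["beta"].notna() & t["se"].notna() & t["z"].notna()
            if both.any():
                dev = np.abs(t.loc[both, "z"] - t.loc[both, "beta"] / t.loc[both, "se"])
                if (dev >= 1e-6).any():
                    raise ValueError("z inconsistent with beta/se")
        if (t["n"] <= 0).any():
            raise ValueError("n_gwas must be positive")
        self.table = t.reset_index(drop=True)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def z(self) -> np.ndarray:
        return self.table["z"].to_numpy(dtype=float)

    @property
    def n_gwas(self) -> float:
        return float(self.table["n"].median())

    def subset(self, snp_ids) -> "GWASSummary":
        order = {s: i for i, s in enumerate(snp_ids)}
        sub = self.table[self.table["snp_id"].isin(order)].copy()
        sub = sub.sort_values("snp_id", key=lambda s: s.map(order))
        return GWASSummary(sub.reset_index(drop=True))


@dataclass
class SimTruth:
    """Ground truth of a simulated architecture, for recovery tests.

    eqtl_effects maps feature_id -> dense per-SNP effect vector on the
    standardized-genotype scale (zeros off the causal support).
    """

    eqtl_effects: dict[str, np.ndarray]
    h2_cis: dict[str, float]
    alpha: dict[str, float]
    direct_snp_effects: np.ndarray
    h2_trait: float
    h2_med_true: float
    seed: int
    snp_ids: np.ndarray | None = None  # ordering of the effect vectors

    def __post_init__(self) -> None:
        for key, h2 in self.h2_cis.items():
            if not 0.0 <= h2 <= 1.0:
                raise ValueError(f"h2_cis out of [0,1] for {key}")
        if self.h2_med_true > self.h2_trait + 1e-9:
            raise ValueError("mediated heritability cannot exceed trait heritability")


@dataclass
class WeightModel:
    """Sparse cis SNP-weight model for one expression feature."""

    feature_id: str
    level: str
    snp_ids: np.ndarray
    weights: np.ndarray
    cv_r2: float
    family: str
    n_train: int
    gene_id: str | None = None

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.cv_r2 > 1.0 + 1e-12:
            raise ValueError("cv_r2 cannot exceed 1")

    @property
    def nonzero(self) -> int:
        return int(np.sum(self.weights != 0.0))


@dataclass
class ModelDB:
    """Collection of weight models keyed by (feature_id, level)."""

    models: dict[tuple[str, str], WeightModel] = field(default_factory=dict)
    retained: dict[tuple[str, str], bool] = field(default_factory=dict)

    def add(self, model: WeightModel) -> None:
        self.models[(model.feature_id, model.level)] = model

    def get(self, feature_id: str, level: str) -> WeightModel:
        return self.models[(feature_id, level)]

    def by_level(self, level: str, retained_only: bool = False) -> list[WeightModel]:
        out = []
        for key, m in self.models.items():
            if m.level != level:
                continue
            if retained_only and not self.retained.get(key, False):
                continue
            out.append(m)
        return out

    def __len__(self) -> int:
        return len(self.models)


@dataclass
class AssociationRecord:
    feature_id: str
    level: str
    z_assoc: float
    p_raw: float
    gene_id: str | None = None
    p_gene_screen: float = np.nan
    p_fwer_within: float = np.nan
    p_fdr: float = np.nan
    p_perm: float = np.nan

    @property
    def chisq(self) -> float:
        return self.z_assoc**2


@dataclass
class EffectiveSampleReport:
    pct_increase: float
    se_jackknife: float
    ci95: tuple[float, float]
    n_features_used: int


@dataclass
class FeatureCorrelation:
    feature_ids: list[str]
    omega: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.feature_ids)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.shape != (k, k):
            raise ValueError("omega shape mismatch")
        if not np.allclose(self.omega, self.omega.T, atol=1e-8):
            raise ValueError("omega must be symmetric")
        if not np.allclose(np.diag(self.omega), 1.0, atol=1e-6):
            raise ValueError("omega must have unit diagonal")


@dataclass
class FineMapResult:
    feature_ids: list[str]
    pip: np.ndarray
    credible_set: list[str]
    level: float = 0.90
    low_mass: bool = False


@dataclass
class QTLRecord:
    feature_id: str
    snp_id: str
    beta: float
    se: float
    p_wald: float


@dataclass
class ColocResult:
    feature_id: str
    locus_id: str
    clpp: float
    gwas_min_p: float
    qtl_min_p: float
    colocalized: bool = False


@dataclass
class GWASLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    lead_snp: str
    lead_p: float


@dataclass
class MediationEstimate:
    h2_total: float
    h2_med: float
    ratio: float
    se_ratio: float
    wald_p: float
    flagged: bool = False
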