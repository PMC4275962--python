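"""Core data containers and I/O for genotypes, phenotypes, gene maps and networks.

Genotypes are stored as an ``n x P`` integer matrix of per-SNP minor-allele
dosage codes together with a SNP-to-gene map.  Three coding schemes are
supported (all with respect to the minor allele ``a``):

========== ==== ===== ====
scheme      AA  Aa/aA  aa
========== ==== ===== ====
additive     0    1    2
dominant     0    1    1
recessive    0    0    1
========== ==== ===== ====
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CODINGS = ("additive", "dominant", "recessive")

#: allowed entries per coding scheme
_SUPPORT = {"additive": {0, 1, 2}, "dominant": {0, 1}, "recessive": {0, 1}}

_GENOTYPE_CLASSES = {"AA": 0, "Aa": 1, "aA": 1, "aa": 2}

_PLINK_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class Phenotype:
    """Binary case/control status (case = 1)."""

    Y: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.int8)
        vals = set(np.unique(self.Y))
        if not vals <= {0, 1}:
            raise ValueError(f"phenotype values must be 0/1, got {sorted(vals)}")
        if len(vals) < 2:
            raise ValueError("phenotype needs at least one case and one control")

    @property
    def n(self) -> int:
        return self.Y.shape[0]


@dataclass
class GenotypeData:
    """Coded genotype matrix plus SNP-to-gene map.

    Attributes
    ----------
    X : (n, P) int array of coded genotypes.
    sample_ids, snp_ids : identifier lists.
    gene_of_snp : (P,) int array mapping each SNP column to a gene index
        in ``0..J-1``; gene indices are dense (every gene has >= 1 SNP).
    gene_ids : list of J gene identifiers.
    coding : one of ``additive``, ``dominant``, ``recessive``.
    """

    X: np.ndarray
    sample_ids: list
    snp_ids: list
    gene_of_snp: np.ndarray
    gene_ids: list
    coding: str = "additive"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.gene_of_snp = np.asarray(self.gene_of_snp, dtype=np.intp)
        n, P = self.X.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != P:
            raise ValueError("id lists do not match matrix dimensions")
        if self.gene_of_snp.shape != (P,):
            raise ValueError("gene_of_snp must have one entry per SNP")
        if self.coding not in CODINGS:
            raise ValueError(f"unknown coding {self.coding!r}")
        if len(self.snp_ids) != len(set(self.snp_ids)):
            raise ValueError("duplicate SNP ids")
        present = np.unique(self.gene_of_snp)
        J = len(self.gene_ids)
        if P and (present.min() < 0 or present.max() >= J):
            raise ValueError("gene_of_snp index out of range")
        if P and len(present) != J:
            raise ValueError("empty gene: every gene index must own >= 1 SNP")
        support = _SUPPORT[self.coding]
        bad = ~np.isin(self.X, list(support))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"entry X[{i},{j}]={self.X[i, j]} outside {sorted(support)} "
                f"for {self.coding} coding"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def P(self) -> int:
        return self.X.shape[1]

    @property
    def J(self) -> int:
        return len(self.gene_ids)

    def snps_of_gene(self, j: int) -> np.ndarray:
        """Column indices of the SNPs mapped to gene ``j``."""
        return np.flatnonzero(self.gene_of_snp == j)


@dataclass
class GeneNetwork:
    """Undirected gene-gene adjacency with zero diagonal."""

    R: np.ndarray
    gene_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=np.int8)
        J = self.R.shape[0]
        if self.R.shape != (J, J):
            raise ValueError("R must be square")
        if not np.array_equal(self.R, self.R.T):
            raise ValueError("R must be symmetric")
        if np.any(np.diag(self.R) != 0):
            raise ValueError("R must have zero diagonal")
        if not set(np.unique(self.R)) <= {0, 1}:
            raise ValueError("R must be binary")
        if not self.gene_ids:
            self.gene_ids = [f"g{j}" for j in range(J)]

    @property
    def J(self) -> int:
        return self.R.shape[0]

    def neighbors(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.R[j])

    @classmethod
    def empty(cls, gene_ids: list) -> "GeneNetwork":
        J = len(gene_ids)
        return cls(np.zeros((J, J), dtype=np.int8), list(gene_ids))


def encode_genotypes(raw, scheme: str = "additive") -> np.ndarray:
    """Recode genotype classes or minor-allele counts under a genetic model.

    ``raw`` may contain string classes (``AA``, ``Aa``/``aA``, ``aa``) or
    integer minor-allele counts 0/1/2.  Additive keeps 0/1/2; dominant maps
    to 0/1/1 and recessive to 0/0/1, elementwise.
    """
    if scheme not in CODINGS:
        raise ValueError(f"unknown coding scheme {scheme!r}")
    raw = np.asarray(raw)
    if raw.dtype.kind in "UOS":
        counts = np.empty(raw.shape, dtype=np.int8)
        flat_raw = raw.ravel()
        flat = counts.ravel()
        for idx, g in enumerate(flat_raw):
            try:
                flat[idx] = _GENOTYPE_CLASSES[str(g)]
            except KeyError:
                loc = np.unravel_index(idx, raw.shape)
                raise ValueError(f"unknown genotype class {g!r} at {loc}") from None
    else:
        counts = raw.astype(np.int8)
        bad = ~np.isin(counts, [0, 1, 2])
        if bad.any():
            loc = tuple(np.argwhere(bad)[0])
            raise ValueError(f"allele count outside 0/1/2 at {loc}")
    if scheme == "additive":
        return counts
    if scheme == "dominant":
        return np.minimum(counts, 1).astype(np.int8)
    return np.maximum(counts - 1, 0).astype(np.int8)  # recessive


def _impute_mode(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Fill missing entries (NaN) with the per-SNP modal code."""
    miss = np.isnan(X)
    frac = float(miss.mean()) if X.size else 0.0
    if frac == 0.0:
        return X.astype(np.int8), 0.0
    out = X.copy()
    for j in range(X.shape[1]):
        col = out[:, j]
        m = np.isnan(col)
        if not m.any():
            continue
        obs = col[~m].astype(int)
        if obs.size == 0:
            mode = 0
        else:
            vals, cnt = np.unique(obs, return_counts=True)
            mode = int(vals[np.argmax(cnt)])  # ties -> smallest code
        col[m] = mode
    return out.astype(np.int8), frac


def load_gene_map(path) -> dict:
    """Read a two-column TSV (snp_id, gene_id) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["snp_id", "gene_id"],
                     dtype=str, comment="#")
    return dict(zip(df["snp_id"], df["gene_id"]))


def load_genotypes(path, gene_map_path, coding: str = "additive"):
    """Load a genotype table plus gene map into :class:`GenotypeData`.

    The genotype table is TSV/CSV with samples as rows and a header row of
    SNP ids; a PLINK ``.raw`` dialect (whitespace-separated, leading columns
    FID IID PAT MAT SEX PHENOTYPE) is auto-detected, in which case the
    phenotype column is returned as a :class:`Phenotype` (else ``None``).
    SNPs absent from the gene map are dropped with a logged count; missing
    genotypes are imputed to the per-SNP mode.
    """
    with open(path) as fh:
        header = fh.readline()
    plink = header.split()[:6] == _PLINK_META_COLS
    if plink:
        df = pd.read_csv(path, sep=r"\s+")
        pheno_raw = df["PHENOTYPE"].to_numpy()
        sample_ids = df["IID"].astype(str).tolist()
        geno = df.drop(columns=_PLINK_META_COLS)
        # PLINK coded 1/2 phenotypes -> 0/1
        if set(np.unique(pheno_raw)) <= {1, 2}:
            pheno_raw = pheno_raw - 1
        phenotype = Phenotype(pheno_raw)
        # .raw columns are SNP_A (counted allele suffix); strip it
        snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in geno.columns]
    else:
        sep = "," if "," in header else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        sample_ids = df.index.astype(str).tolist()
        snp_ids = [str(c) for c in df.columns]
        geno = df
        phenotype = None

    X = geno.to_numpy(dtype=float)
    gene_map = load_gene_map(gene_map_path)
    keep = [k for k, s in enumerate(snp_ids) if s in gene_map]
    dropped = len(snp_ids) - len(keep)
    if dropped:
        logger.warning("dropping %d SNP(s) absent from the gene map", dropped)
        warnings.warn(f"{dropped} SNP(s) without gene-map entry dropped",
                      stacklevel=2)
    X = X[:, keep]
    snp_ids = [snp_ids[k] for k in keep]
    if X.shape[1] != len(set(snp_ids)):
        raise ValueError("duplicate SNP ids in genotype table")

    X, frac = _impute_mode(X)
    if frac:
        logger.info("imputed %.3f%% missing genotypes to per-SNP mode", 100 * frac)
    X = encode_genotypes(X, coding)

    gene_labels = [gene_map[s] for s in snp_ids]
    gene_ids = sorted(set(gene_labels))
    gene_index = {g: j for j, g in enumerate(gene_ids)}
    gene_of_snp = np.array([gene_index[g] for g in gene_labels], dtype=np.intp)
    data = GenotypeData(X, sample_ids, snp_ids, gene_of_snp, gene_ids, coding)
    return (data, phenotype) if plink else data


def write_genotypes(data: GenotypeData, path, gene_map_path=None) -> None:
    """Write genotype TSV (and optionally the gene map) in load_genotypes format."""
    df = pd.DataFrame(data.X, index=data.sample_ids, columns=data.snp_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
    if gene_map_path is not None:
        with open(gene_map_path, "w") as fh:
            for s, j in zip(data.snp_ids, data.gene_of_snp):
                fh.write(f"{s}\t{data.gene_ids[j]}\n")


def load_phenotype(path) -> Phenotype:
    """Single-column phenotype file (0/1 per sample, optional header)."""
    vals = pd.read_csv(path, header=None).iloc[:, -1]
    if not np.issubdtype(vals.dtype, np.number):
        vals = pd.to_numeric(vals.iloc[1:])
    return Phenotype(vals.to_numpy())


def write_phenotype(pheno: Phenotype, path) -> None:
    np.savetxt(path, pheno.Y, fmt="%d")


def load_network(path, gene_ids) -> GeneNetwork:
    """Read an edge-list TSV (gene_id_a, gene_id_b) into a GeneNetwork.

    Unknown genes are ignored with a warning; self-loops and duplicate
    edges are dropped.  An empty file yields R = 0, under which the MRF
    prior reduces to independent gene selection.
    """
    gene_ids = list(gene_ids)
    index = {g: j for j, g in enumerate(gene_ids)}
    J = len(gene_ids)
    R = np.zeros((J, J), dtype=np.int8)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return GeneNetwork(R, gene_ids)
    unknown = 0
    for a, b in df.iloc[:, :2].itertuples(index=False):
        if a not in index or b not in index:
            unknown += 1
            continue
        i, j = index[a], index[b]
        if i == j:
            continue
        R[i, j] = R[j, i] = 1
    if unknown:
        warnings.warn(f"{unknown} edge(s) referencing unknown genes ignored",
                      stacklevel=2)
    return GeneNetwork(R, gene_ids)


def write_network(net: GeneNetwork, path) -> None:
    with open(path, "w") as fh:
        ii, jj = np.nonzero(np.triu(net.R))
        for i, j in zip(ii, jj):
            fh.write(f"{net.gene_ids[i]}\t{net.gene_ids[j]}\n")
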