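"""96-trinucleotide mutation spectra and spectrum-based sample clustering.

Each somatic SNV is classified by its substitution type and immediate
5'/3' flanking bases.  Substitutions are collapsed onto the pyrimidine
strand (a G>T with flanks A_C is counted as C>A with flanks G_T after
reverse complementing), giving 6 types x 16 contexts = 96 categories.
Samples are then compared by their spectra: principal components on
proportion-normalized spectra, and hierarchical clustering with cosine
dissimilarity under Ward's linkage update.  Note Ward linkage formally
assumes squared Euclidean distances; it is applied here to the cosine
dissimilarity matrix deliberately, to reproduce the published
procedure rather than a corrected variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: canonical 96-category order: substitution block, then 5' base, then 3' base
SPECTRUM_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
_LABEL_INDEX = {lab: i for i, lab in enumerate(SPECTRUM_LABELS)}


def classify_context(ref: str, alt: str, context5: str, context3: str) -> int:
    """Map one SNV with flanking bases to its 96-spectrum index.

    Purine-reference mutations are reverse-complemented first, so every
    substitution lands in one of the six pyrimidine-referenced types.
    Raises ValueError for non-ACGT bases or ref == alt.
    """
    for b in (ref, alt, context5, context3):
        if b not in COMPLEMENT:
            raise ValueError(f"ambiguous or invalid base {b!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if ref in "AG":  # collapse to pyrimidine strand
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        context5, context3 = COMPLEMENT[context3], COMPLEMENT[context5]
    return _LABEL_INDEX[f"{context5}[{ref}>{alt}]{context3}"]


@dataclass
class Spectrum96:
    """Trinucleotide mutation counts for one sample."""

    sample_id: str
    counts: np.ndarray  # shape (96,), non-negative ints
    n_skipped: int = 0

    @property
    def six_type_marginal(self) -> dict[str, int]:
        by_type = self.counts.reshape(6, 16).sum(axis=1)
        return dict(zip(SUBSTITUTIONS, by_type.astype(int)))

    def total(self) -> int:
        return int(self.counts.sum())


def spectrum(variants: pd.DataFrame, sample_id: str | None = None) -> Spectrum96:
    """Build a 96-category spectrum from a variant table.

    Only SNV rows contribute; indels and records with ambiguous bases
    are skipped (the latter with a warning) and tallied in
    ``n_skipped``.
    """
    counts = np.zeros(96, dtype=np.int64)
    skipped = 0
    snvs = variants[variants["vclass"] == "SNV"] if len(variants) else variants
    for r in snvs.itertuples(index=False):
        try:
            counts[classify_context(r.ref, r.alt, r.context5, r.context3)] += 1
        except ValueError as exc:
            logger.warning("skipping %s:%s %s>%s: %s", r.chrom, r.pos, r.ref, r.alt, exc)
            skipped += 1
    if sample_id is None:
        sample_id = str(variants["sample"].iloc[0]) if len(variants) else "sample"
    return Spectrum96(sample_id, counts, skipped)


def spectrum_matrix(spectra: list[Spectrum96]) -> pd.DataFrame:
    """Samples x 96 count matrix in canonical column order."""
    return pd.DataFrame(
        [s.counts for s in spectra],
        index=[s.sample_id for s in spectra],
        columns=list(SPECTRUM_LABELS),
    )


@dataclass
class SpectrumClustering:
    sample_ids: list[str]
    pca_coordinates: pd.DataFrame  # samples x components
    linkage: np.ndarray  # scipy linkage matrix
    newick: str
    cluster_labels: dict[str, int]  # 2-group cut


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage tree to Newick with merge-height branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def cluster_samples(
    spectra: list[Spectrum96], n_components: int = 2
) -> SpectrumClustering:
    """PCA + hierarchical clustering of samples by mutation spectrum.

    Spectra are normalized to proportions; pairwise cosine
    dissimilarities feed Ward-linkage agglomeration, and the
    proportion matrix (mean-centered) feeds the PCA.  All-zero spectra
    are excluded with a warning.  Output is deterministic for a fixed
    input order.
    """
    kept = []
    for s in spectra:
        if s.counts.sum() == 0:
            logger.warning("excluding all-zero spectrum %s from clustering", s.sample_id)
        else:
            kept.append(s)
    if len(kept) < 2:
        raise ValueError("cluster_samples requires >= 2 non-empty spectra")

    ids = [s.sample_id for s in kept]
    mat = np.array([s.counts / s.counts.sum() for s in kept], dtype=float)

    from sklearn.decomposition import PCA

    n_comp = min(n_components, len(kept) - 1, mat.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(mat)
    pca_df = pd.DataFrame(
        coords, index=ids, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )

    dist = pdist(mat, metric="cosine")
    Z = hierarchy.linkage(dist, method="ward")
    labels2 = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return SpectrumClustering(
        sample_ids=ids,
        pca_coordinates=pca_df,
        linkage=Z,
        newick=_linkage_to_newick(Z, ids),
        cluster_labels=dict(zip(ids, (int(v) for v in labels2))),
    )
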