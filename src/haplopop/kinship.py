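"""KING-robust kinship estimation, relationship-degree classification, and
the closest-relative graph used to reconstruct cultivation history.

The estimator is the within-pair ("robust") form whose denominator is the
smaller of the two per-sample heterozygosity counts; it is insensitive to
sample composition and population structure, which matters for panels mixing
diverged wild populations with admixed cultivars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, SampleSheet, VariantTable

DEGREES = ("duplicate", "1", "2", "3", "unrelated")

# Degree cutoffs at 2^-(d + 3/2): the geometric midpoints between the
# expected kinship coefficients 1/2, 1/4, 1/8, 1/16 of successive degrees.
_CUTOFFS = (0.3536, 0.1768, 0.0884, 0.0442)


@dataclass
class KinshipEstimate:
    phi: float | None
    n_both_het: int        # sites where both samples are Aa
    n_opposite_hom: int    # sites AA vs aa
    n_het_i: int
    n_het_j: int
    n_joint: int           # jointly called biallelic sites

    @property
    def degree(self) -> str:
        return classify_relationship(self.phi)


def classify_relationship(phi: float | None) -> str:
    """Relationship degree from a kinship coefficient.

    duplicate/MZ above 0.3536; 1st degree in (0.1768, 0.3536]; 2nd in
    (0.0884, 0.1768]; 3rd in (0.0442, 0.0884]; unrelated at or below 0.0442
    (and for undefined phi).
    """
    if phi is None or not np.isfinite(phi):
        return "unrelated"
    if phi > _CUTOFFS[0]:
        return "duplicate"
    for deg, hi, lo in zip(("1", "2", "3"), _CUTOFFS, _CUTOFFS[1:]):
        if lo < phi <= hi:
            return deg
    return "unrelated"


def king_kinship_pair(gt_i: np.ndarray, gt_j: np.ndarray) -> KinshipEstimate:
    """KING-robust phi for one pair from (n_sites, 2) genotype arrays.

    phi = (N_AaAa - 2 N_AA,aa) / (2 min(N_Aa^i, N_Aa^j))
          + 1/2 - (N_Aa^i + N_Aa^j) / (4 min(N_Aa^i, N_Aa^j)).

    Undefined (phi None) when either sample has no heterozygous site among
    jointly called sites.
    """
    called = np.all(gt_i != MISSING, axis=1) & np.all(gt_j != MISSING, axis=1)
    gi, gj = gt_i[called], gt_j[called]
    het_i = gi[:, 0] != gi[:, 1]
    het_j = gj[:, 0] != gj[:, 1]
    dos_i = (gi > 0).sum(axis=1)
    dos_j = (gj > 0).sum(axis=1)
    n_both_het = int((het_i & het_j).sum())
    n_opp = int((~het_i & ~het_j & (dos_i != dos_j)).sum())
    n_i, n_j = int(het_i.sum()), int(het_j.sum())
    m = min(n_i, n_j)
    if m == 0:
        return KinshipEstimate(None, n_both_het, n_opp, n_i, n_j, int(called.sum()))
    phi = (n_both_het - 2 * n_opp) / (2 * m) + 0.5 - (n_i + n_j) / (4 * m)
    return KinshipEstimate(float(phi), n_both_het, n_opp, n_i, n_j, int(called.sum()))


def ibs_fractions(gt_i: np.ndarray, gt_j: np.ndarray) -> dict:
    """IBS0/IBS1/IBS2 site fractions over jointly called biallelic sites."""
    called = np.all(gt_i != MISSING, axis=1) & np.all(gt_j != MISSING, axis=1)
    di = (gt_i[called] > 0).sum(axis=1)
    dj = (gt_j[called] > 0).sum(axis=1)
    diff = np.abs(di - dj)
    n = max(1, int(called.sum()))
    return {
        "ibs0": float((diff == 2).sum() / n),
        "ibs1": float((diff == 1).sum() / n),
        "ibs2": float((diff == 0).sum() / n),
    }


def kinship_matrix(vt: VariantTable, samples: list | None = None) -> pd.DataFrame:
    """All-pairs KING-robust kinship with supporting counts and IBS fractions.

    Returns a tidy frame with one row per unordered pair: sample_i, sample_j,
    phi, degree, the heterozygosity/opposite-homozygote counts and IBS0/1/2.
    """
    vt = vt.take_sites(vt.is_biallelic_snp())
    ids = samples or vt.samples
    idx = vt.sample_index(ids)
    rows = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            gi, gj = vt.genotypes[:, idx[a], :], vt.genotypes[:, idx[b], :]
            est = king_kinship_pair(gi, gj)
            row = {
                "sample_i": ids[a],
                "sample_j": ids[b],
                "phi": est.phi,
                "degree": est.degree,
                "n_both_het": est.n_both_het,
                "n_opposite_hom": est.n_opposite_hom,
                "n_het_i": est.n_het_i,
                "n_het_j": est.n_het_j,
                "n_joint": est.n_joint,
            }
            row.update(ibs_fractions(gi, gj))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RelativeGraph:
    """Directed graph linking each sample to its highest-phi positive relative."""

    edges: pd.DataFrame  # sample, relative, phi, degree
    isolated: list
    annotations: pd.DataFrame | None = None

    def to_dot(self) -> str:
        lines = ["digraph closest_relatives {"]
        style = {"duplicate": "bold", "1": "solid", "2": "dashed", "3": "dotted"}
        for _, r in self.edges.iterrows():
            lines.append(
                f'  "{r["sample"]}" -> "{r["relative"]}" '
                f'[label="{r["degree"]} (phi={r["phi"]:.3f})", style={style.get(r["degree"], "solid")}];'
            )
        for s in self.isolated:
            lines.append(f'  "{s}";')
        lines.append("}")
        return "\n".join(lines)


def closest_relative_graph(km: pd.DataFrame, sheet: SampleSheet | None = None) -> RelativeGraph:
    """For every sample, an edge to its argmax-phi partner when phi > 0.

    Ties are broken by lexical order of the partner's sample id; samples with
    no positive-phi partner are isolated nodes.
    """
    samples = sorted(set(km["sample_i"]) | set(km["sample_j"]))
    phi = {}
    for _, r in km.iterrows():
        if r["phi"] is None or not np.isfinite(r["phi"]):
            continue
        phi[(r["sample_i"], r["sample_j"])] = (r["phi"], r["degree"])
        phi[(r["sample_j"], r["sample_i"])] = (r["phi"], r["degree"])
    rows, isolated = [], []
    for s in samples:
        partners = [(p, v) for (a, p), v in phi.items() if a == s and v[0] > 0]
        if not partners:
            isolated.append(s)
            continue
        partners.sort(key=lambda t: (-t[1][0], t[0]))
        best, (bphi, bdeg) = partners[0]
        rows.append({"sample": s, "relative": best, "phi": bphi, "degree": bdeg})
    edges = pd.DataFrame(rows, columns=["sample", "relative", "phi", "degree"])
    ann = None
    if sheet is not None:
        ann = sheet.table.loc[[s for s in samples if s in sheet.table.index]]
    return RelativeGraph(edges=edges, isolated=isolated, annotations=ann)
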