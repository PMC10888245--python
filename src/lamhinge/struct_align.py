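"""Rigid-body Cα superposition and RMSD over matched residue ranges.

Correspondence is by residue number under an explicit chain map (predicted
models often renumber from 1, so the map carries a per-chain offset); no
sequence alignment is performed.  Superposition is a single-pass
least-squares Kabsch fit over all chains jointly — one rigid transform, no
outlier trimming — with the reflection case rejected through the usual
determinant correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from lamhinge.core_io import AtomisticStructure, ResidueRange

logger = logging.getLogger("lamhinge")

__all__ = [
    "ChainMap",
    "CorrespondenceSet",
    "build_correspondence",
    "superpose_rmsd",
    "SuperpositionResult",
]


@dataclass(frozen=True)
class ChainMap:
    """Pairs a predicted chain with a reference chain.

    ``offset`` converts predicted residue numbers to reference numbering:
    ``ref_resnum = pred_resnum + offset``.
    """

    pred_chain: str
    ref_chain: str
    offset: int = 0


@dataclass
class CorrespondenceSet:
    """Ordered Cα pairs (predicted, reference) ready for superposition."""

    pred_coords: np.ndarray  # (n, 3) Å
    ref_coords: np.ndarray  # (n, 3) Å
    labels: list[tuple[str, int, str, int]]  # pred chain/res, ref chain/res

    def __post_init__(self) -> None:
        self.pred_coords = np.asarray(self.pred_coords, dtype=float)
        self.ref_coords = np.asarray(self.ref_coords, dtype=float)
        if self.pred_coords.shape != self.ref_coords.shape:
            raise ValueError("coordinate arrays must match in shape")
        if len(self.pred_coords) < 3:
            raise ValueError("need at least 3 correspondence pairs")

    def __len__(self) -> int:
        return len(self.pred_coords)


def _ca_lookup(structure: AtomisticStructure, chain: str) -> dict[int, np.ndarray]:
    m = (structure.chain_ids.astype(str) == chain) & structure.ca_mask()
    sub = structure.select(m)
    return {int(r): c for r, c in zip(sub.res_numbers, sub.coords)}


def build_correspondence(
    pred: AtomisticStructure,
    ref: AtomisticStructure,
    ranges: list[ResidueRange],
    chain_map: list[ChainMap],
) -> CorrespondenceSet:
    """Match Cα atoms of a predicted and a reference structure.

    ``ranges`` address the *reference* numbering.  Pairs are restricted to
    residues with a Cα present on both sides; dropped residues are logged
    with the reason.  Fewer than 3 shared pairs is an error.
    """
    by_ref_chain = {cm.ref_chain: cm for cm in chain_map}
    pred_tables = {cm.pred_chain: _ca_lookup(pred, cm.pred_chain)
                   for cm in chain_map}
    ref_tables = {cm.ref_chain: _ca_lookup(ref, cm.ref_chain)
                  for cm in chain_map}

    pred_pts, ref_pts, labels = [], [], []
    dropped = []
    for rr in ranges:
        cm = by_ref_chain.get(rr.chain_id)
        if cm is None:
            raise ValueError(f"range {rr} has no chain_map entry")
        for ref_res in range(rr.first, rr.last + 1):
            pred_res = ref_res - cm.offset
            rc = ref_tables[cm.ref_chain].get(ref_res)
            pc = pred_tables[cm.pred_chain].get(pred_res)
            if rc is None or pc is None:
                side = "reference" if rc is None else "predicted"
                dropped.append((rr.chain_id, ref_res, side))
                continue
            pred_pts.append(pc)
            ref_pts.append(rc)
            labels.append((cm.pred_chain, pred_res, cm.ref_chain, ref_res))
    for chain, res, side in dropped:
        logger.info("correspondence: dropped %s %d (no CA in %s)", chain, res, side)
    if len(pred_pts) < 3:
        raise ValueError(
            f"only {len(pred_pts)} shared CA pairs (need >= 3); "
            f"{len(dropped)} residues dropped"
        )
    return CorrespondenceSet(np.array(pred_pts), np.array(ref_pts), labels)


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,), Å; applies as R·x + t
    rmsd: float  # Å
    n_pairs: int


def superpose_rmsd(cs: CorrespondenceSet) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch) of the predicted onto the
    reference coordinates, and the residual Cα RMSD in Å.

    The SVD determinant correction enforces a proper rotation (reflections
    rejected).  Degenerate (collinear) point sets are an error, as the
    in-plane orientation would be unconstrained.
    """
    p = cs.pred_coords
    r = cs.ref_coords
    pc, rc = p.mean(axis=0), r.mean(axis=0)
    p0, r0 = p - pc, r - rc

    # collinearity check: the two largest singular values must be non-trivial
    sv = np.linalg.svd(p0, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1e-30):
        raise ValueError("degenerate (collinear) point set")

    h = p0.T @ r0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = rc - rot @ pc
    moved = p0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - r0) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=t, rmsd=rmsd,
                               n_pairs=len(cs))
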