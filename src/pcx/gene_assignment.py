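"""CpG-to-gene assignment by a three-rule proximity cascade.

Rule 1 (gene_body_4kb): a CpG within 4 kb of a gene body (distance 0 if
inside) is assigned to that gene. Rule 2 (neighbor_cpg): a remaining CpG
within ``neighbor_radius`` of a CpG already assigned by rule 1 inherits that
CpG's gene; inheritance never chains through other rule-2 assignments.
Rule 3 (nearest_prc2_200kb): otherwise the CpG goes to the nearest PRC2
target gene body within 200 kb. Anything else is unassigned. Ties are broken
by smaller distance, then lexicographic gene id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DataError, validate_annotation

RULE_GENE_BODY = "gene_body_4kb"
RULE_NEIGHBOR = "neighbor_cpg"
RULE_PRC2 = "nearest_prc2_200kb"
RULE_NONE = "unassigned"

BODY_RADIUS = 4_000
PRC2_RADIUS = 200_000


def _nearest_gene(chroms: np.ndarray, positions: np.ndarray,
                  annotation: pd.DataFrame):
    """Nearest gene body per CpG with (distance, gene_id) tie-breaking.

    Distance to a half-open body [start, end) is 0 inside, else the gap to
    the closest covered base. Returns (gene_id array, distance array);
    positions on chromosomes without genes get distance inf.
    """
    gene = np.full(len(positions), "", dtype=object)
    dist = np.full(len(positions), np.inf)
    for chrom, grp in annotation.groupby("chrom", sort=False):
        mask = chroms == chrom
        if not mask.any():
            continue
        # genes pre-sorted by gene_id so argmin lands on the smallest id
        grp = grp.sort_values("gene_id", kind="mergesort")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        ids = grp["gene_id"].to_numpy()
        pos = positions[mask][:, None]
        d = np.maximum.reduce([starts[None, :] - pos,
                               pos - (ends[None, :] - 1),
                               np.zeros((int(mask.sum()), len(grp)), dtype=np.int64)])
        best = np.argmin(d, axis=1)
        dist[mask] = d[np.arange(len(best)), best]
        gene[mask] = ids[best]
    return gene, dist


def assign_all(cpgs: pd.DataFrame,
               annotation: pd.DataFrame,
               prc2_targets,
               body_radius: int = BODY_RADIUS,
               neighbor_radius: int = 1_000,
               prc2_radius: int = PRC2_RADIUS) -> pd.DataFrame:
    """Assign every CpG to a gene via the three-rule cascade.

    Two passes: pass 1 applies the gene-body rule everywhere; pass 2 walks
    the remainder in coordinate order applying the neighbor rule (against
    pass-1 assignments only) and then the PRC2-proximity rule. Returns a
    frame (chrom, pos, gene_id, rule, distance) aligned to sorted CpG order.
    """
    ann = validate_annotation(annotation)
    targets = set(prc2_targets)
    unknown = targets - set(ann["gene_id"])
    if unknown:
        raise DataError(f"PRC2 targets absent from annotation: {sorted(unknown)[:5]}")
    cp = (cpgs.loc[:, ["chrom", "pos"]]
          .sort_values(["chrom", "pos"], kind="mergesort")
          .reset_index(drop=True))
    chroms = cp["chrom"].to_numpy()
    positions = cp["pos"].to_numpy(dtype=np.int64)

    gene = np.full(len(cp), "", dtype=object)
    rule = np.full(len(cp), RULE_NONE, dtype=object)
    dist = np.full(len(cp), np.nan)

    if len(ann) > 0:
        near_gene, near_d = _nearest_gene(chroms, positions, ann)
        body_hit = near_d <= body_radius
        gene[body_hit] = near_gene[body_hit]
        rule[body_hit] = RULE_GENE_BODY
        dist[body_hit] = near_d[body_hit]

        targets_ann = ann.loc[ann["gene_id"].isin(targets)]
        if len(targets_ann) > 0:
            prc2_gene, prc2_d = _nearest_gene(chroms, positions, targets_ann)
        else:
            prc2_gene = np.full(len(cp), "", dtype=object)
            prc2_d = np.full(len(cp), np.inf)

        remaining = np.nonzero(~body_hit)[0]
        for chrom in pd.unique(chroms):
            cmask = chroms == chrom
            anchors = positions[cmask & body_hit]
            anchor_genes = gene[cmask & body_hit]
            for i in remaining:
                if chroms[i] != chrom:
                    continue
                if anchors.size:
                    k = np.searchsorted(anchors, positions[i])
                    cands = []
                    if k > 0:
                        cands.append((positions[i] - anchors[k - 1],
                                      anchors[k - 1], anchor_genes[k - 1]))
                    if k < anchors.size:
                        cands.append((anchors[k] - positions[i],
                                      anchors[k], anchor_genes[k]))
                    d_n, _, g_n = min(cands, key=lambda c: (c[0], c[2], c[1]))
                    if d_n <= neighbor_radius:
                        gene[i] = g_n
                        rule[i] = RULE_NEIGHBOR
                        dist[i] = d_n
                        continue
                if prc2_d[i] <= prc2_radius:
                    gene[i] = prc2_gene[i]
                    rule[i] = RULE_PRC2
                    dist[i] = prc2_d[i]

    out = cp.copy()
    out["gene_id"] = np.where(rule == RULE_NONE, pd.NA, gene)
    out["rule"] = rule
    out["distance"] = dist
    return out


def assign_cpg_to_gene(chrom: str, pos: int,
                       annotation: pd.DataFrame,
                       existing_assignments: pd.DataFrame | None,
                       prc2_targets,
                       body_radius: int = BODY_RADIUS,
                       neighbor_radius: int = 1_000,
                       prc2_radius: int = PRC2_RADIUS) -> dict:
    """Assign a single CpG; ``existing_assignments`` supplies the
    gene-body-assigned CpGs the neighbor rule may inherit from."""
    ann = validate_annotation(annotation)
    if len(ann) > 0:
        g, d = _nearest_gene(np.array([chrom], dtype=object),
                             np.array([pos], dtype=np.int64), ann)
        if d[0] <= body_radius:
            return {"chrom": chrom, "pos": pos, "gene_id": g[0],
                    "rule": RULE_GENE_BODY, "distance": float(d[0])}
    if existing_assignments is not None and len(existing_assignments) > 0:
        anchors = existing_assignments.loc[
            (existing_assignments["rule"] == RULE_GENE_BODY)
            & (existing_assignments["chrom"] == chrom)]
        if len(anchors) > 0:
            dd = np.abs(anchors["pos"].to_numpy() - pos)
            order = np.lexsort((anchors["pos"].to_numpy(),
                                anchors["gene_id"].to_numpy(), dd))
            best = order[0]
            if dd[best] <= neighbor_radius:
                return {"chrom": chrom, "pos": pos,
                        "gene_id": anchors["gene_id"].to_numpy()[best],
                        "rule": RULE_NEIGHBOR, "distance": float(dd[best])}
    targets_ann = ann.loc[ann["gene_id"].isin(set(prc2_targets))]
    if len(targets_ann) > 0:
        g, d = _nearest_gene(np.array([chrom], dtype=object),
                             np.array([pos], dtype=np.int64), targets_ann)
        if d[0] <= prc2_radius:
            return {"chrom": chrom, "pos": pos, "gene_id": g[0],
                    "rule": RULE_PRC2, "distance": float(d[0])}
    return {"chrom": chrom, "pos": pos, "gene_id": None,
            "rule": RULE_NONE, "distance": float("nan")}
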