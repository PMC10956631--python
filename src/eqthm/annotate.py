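"""CpG annotation: gene compartments, CGI classes, collapsed ChromHMM states,
strand-aware CpG-gene distances, and the cis pair universe.

Coordinates are 1-based inclusive internally (array-annotation convention);
BED exports convert to 0-based half-open at the boundary. "Upstream" and
"downstream" are gene-relative: upstream means 5' of the TSS on the gene's
strand, with negative bp distances; downstream of the TTS is positive bp;
positions inside the gene are expressed as the proportion of the way through
the gene, so a CpG exactly at the TSS is inside with proportion 0.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

#: raw EPIC-style gene-compartment vocabulary -> collapsed classes
COMPARTMENT_COLLAPSE = {
    "TSS200": "TSS",
    "TSS1500": "TSS",
    "5'UTR": "5'UTR",
    "1stExon": "gene body",
    "Body": "gene body",
    "ExonBnd": "gene body",
    "3'UTR": "3'UTR",
}

#: chromatin-state collapsing; states not listed pass through unchanged
CHROMHMM_COLLAPSE = {
    "enhancers": "enhancers",
    "genic enhancers": "enhancers",
    "strong transcription": "transcribed",
    "weak transcription": "transcribed",
    "bivalent enhancer": "poised TSS/enhancers",
    "bivalent TSS": "poised TSS/enhancers",
    "polycomb repressed": "polycomb repressed",
    "weak polycomb repressed": "polycomb repressed",
}

CGI_CLASSES = ("island", "shore", "shelf", "open sea")


def collapse_gene_compartments(raw_labels: Iterable[str]) -> set[str]:
    """Map raw array compartment labels to the collapsed 4-class vocabulary.

    A CpG may carry several labels (one per associated gene transcript); the
    collapsed classes are returned as a set, so e.g. {TSS1500, 5'UTR} keeps
    both TSS and 5'UTR.
    """
    out = set()
    for label in raw_labels:
        if label not in COMPARTMENT_COLLAPSE:
            raise ValueError(f"unknown gene-compartment label: {label!r}")
        out.add(COMPARTMENT_COLLAPSE[label])
    return out


def collapse_chromhmm(raw_state: str) -> str:
    return CHROMHMM_COLLAPSE.get(raw_state, raw_state)


def assign_cgi_region(dist_to_island):
    """CGI class from distance (bp) to the nearest island; 0 means inside.

    0 -> island; (0, 2000] -> shore; (2000, 4000] -> shelf; > 4000 -> open
    sea. Boundary distances (exactly 2 kb / 4 kb) belong to the nearer-island
    class ("within 2 kb" taken as inclusive).
    """
    d = np.asarray(dist_to_island)
    if np.any(d < 0):
        raise ValueError("distance to island must be >= 0")
    out = np.select(
        [d == 0, d <= 2000, d <= 4000],
        ["island", "shore", "shelf"],
        default="open sea",
    )
    if np.isscalar(dist_to_island) or np.ndim(dist_to_island) == 0:
        return str(out[()])
    return out


def map_cpg_gene_distance(pos: int, tss: int, tts: int, strand: str = "+"):
    """Zone and distance of a CpG relative to one gene.

    Returns (zone, distance) with zone in {upstream, inside, downstream}.
    Upstream distances are negative bp to the TSS, downstream positive bp
    from the TTS, and inside positions are the proportion through the gene
    in [0, 1] (pos == tss -> 0, pos == tts -> 1), all on the gene's strand.
    """
    s = 1 if strand == "+" else -1
    length = (tts - tss) * s
    if length <= 0:
        raise ValueError(f"gene has tts {'<=' if s == 1 else '>='} tss "
                         f"({tss=}, {tts=}, {strand=})")
    d_tss = (pos - tss) * s
    d_tts = (pos - tts) * s
    if d_tss < 0:
        return "upstream", d_tss
    if d_tts > 0:
        return "downstream", d_tts
    return "inside", d_tss / length


def build_cis_pairs(cpgs: pd.DataFrame, genes: pd.DataFrame,
                    window: int = 1_000_000) -> pd.DataFrame:
    """All qualifying (CpG, gene) cis pairs.

    A pair qualifies if the CpG is inside the gene, at most ``window`` bp
    upstream of its TSS, or at most ``window`` bp downstream of its TTS
    (both boundaries inclusive). A CpG may pair with multiple genes. Expects
    ``cpgs`` with columns cpg_id/chrom/pos and ``genes`` with
    gene_id/chrom/strand/tss/tts.
    """
    out = []
    cp = cpgs.sort_values("pos", kind="stable")
    for chrom, genes_c in genes.groupby("chrom", sort=False):
        cpc = cp[cp["chrom"] == chrom]
        pos = cpc["pos"].to_numpy()
        ids = cpc["cpg_id"].to_numpy()
        for g in genes_c.itertuples(index=False):
            s = 1 if g.strand == "+" else -1
            left = min(g.tss, g.tts) - window
            right = max(g.tss, g.tts) + window
            lo = np.searchsorted(pos, left, side="left")
            hi = np.searchsorted(pos, right, side="right")
            if lo == hi:
                continue
            p = pos[lo:hi]
            d_tss = (p - g.tss) * s
            d_tts = (p - g.tts) * s
            length = (g.tts - g.tss) * s
            zone = np.where(d_tss < 0, "upstream",
                            np.where(d_tts > 0, "downstream", "inside"))
            dist = np.where(d_tss < 0, d_tss.astype(float),
                            np.where(d_tts > 0, d_tts.astype(float),
                                     d_tss / length))
            out.append(pd.DataFrame({
                "cpg_id": ids[lo:hi], "gene_id": g.gene_id,
                "zone": zone, "distance": dist, "pos": p,
            }))
    if not out:
        return pd.DataFrame(columns=["cpg_id", "gene_id", "zone", "distance", "pos"])
    pairs = pd.concat(out, ignore_index=True)
    return pairs.sort_values(["gene_id", "pos"], kind="stable").reset_index(drop=True)


def regions_to_bed(regions: pd.DataFrame, path: str) -> None:
    """Write regions (1-based inclusive start/end) as BED6 (0-based half-open),
    score = -log10 of the Sidak-adjusted regional p."""
    with open(path, "w") as fh:
        for r in regions.itertuples(index=False):
            score = -np.log10(max(float(r.p_sidak), 1e-300))
            fh.write(f"{r.chrom}\t{int(r.start) - 1}\t{int(r.end)}\t"
                     f"{r.gene_id}\t{score:.4f}\t+\n")
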