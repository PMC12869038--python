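"""FUMA-style locus definition and positional gene mapping.

From a conjFDR result table: greedy LD clumping picks independent
significant SNPs (conjFDR < 0.05, pairwise r² < 0.6) and lead SNPs
(r² < 0.1 among the independents); candidate SNPs (conjFDR < 0.10 tagged
at r² > 0.6 by an independent SNP) define locus spans; loci on one
chromosome whose spans lie within 250 kb are merged, the member with the
minimum conjFDR becoming the merged lead.  Candidate SNPs are then mapped
to genes positionally within a window around each gene body.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LdPanel",
    "BlockLdPanel",
    "PairwiseLdPanel",
    "Locus",
    "ld_clump",
    "define_loci",
    "positional_map",
]


class LdPanel:
    """Interface: symmetric r² lookup with unit diagonal; unknown pairs -> 0."""

    def r2(self, snp_a: str, snp_b: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass
class BlockLdPanel(LdPanel):
    """LD from a block-diagonal AR(1) model: r²(i, j) = decay^(2|i-j|)
    within a block, 0 across blocks."""

    snp_ids: np.ndarray
    block: np.ndarray
    index_in_block: np.ndarray
    decay: float
    _pos: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._pos = {s: i for i, s in enumerate(self.snp_ids)}

    def r2(self, snp_a: str, snp_b: str) -> float:
        ia = self._pos.get(snp_a)
        ib = self._pos.get(snp_b)
        if ia is None or ib is None:
            return 0.0
        if ia == ib:
            return 1.0
        if self.block[ia] != self.block[ib]:
            return 0.0
        d = abs(int(self.index_in_block[ia]) - int(self.index_in_block[ib]))
        return float(self.decay ** (2 * d))

    def to_frame(self, min_r2: float = 0.05) -> pd.DataFrame:
        """Pairwise TSV form (SNP_A, SNP_B, R2) within blocks, thresholded."""
        rows = []
        if self.decay <= 0:
            return pd.DataFrame(columns=["SNP_A", "SNP_B", "R2"])
        max_d = int(np.ceil(np.log(min_r2) / (2 * np.log(self.decay)))) if self.decay < 1 else 1
        for i in range(len(self.snp_ids)):
            for d in range(1, max_d + 1):
                j = i + d
                if j >= len(self.snp_ids) or self.block[i] != self.block[j]:
                    break
                rows.append((self.snp_ids[i], self.snp_ids[j], self.decay ** (2 * d)))
        return pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R2"])


class PairwiseLdPanel(LdPanel):
    """LD from a pairwise table (SNP_A, SNP_B, R2); missing pairs are 0."""

    def __init__(self, pairs: pd.DataFrame) -> None:
        self._r2: dict[tuple[str, str], float] = {}
        for a, b, r2 in pairs[["SNP_A", "SNP_B", "R2"]].itertuples(index=False):
            key = (a, b) if a <= b else (b, a)
            self._r2[key] = float(r2)

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        key = (snp_a, snp_b) if snp_a <= snp_b else (snp_b, snp_a)
        return self._r2.get(key, 0.0)


@dataclass
class Locus:
    """Merged genomic locus: span of member candidate SNPs (1-based
    inclusive), lead = member with minimum conjFDR."""

    chrom: str
    start: int
    end: int
    lead_snp: str
    lead_conjfdr: float
    independent_snps: list[str]
    candidate_snps: list[str]


def _greedy_prune(table: pd.DataFrame, ld: LdPanel, r2_threshold: float) -> list[str]:
    """Greedy selection ascending by conjFDR (ties by snp_id); each pick
    removes remaining SNPs with r² >= threshold to it."""
    remaining = list(table.sort_values(["conjfdr", "SNP"], kind="stable")["SNP"])
    selected: list[str] = []
    while remaining:
        best = remaining.pop(0)
        selected.append(best)
        kept = []
        for s in remaining:
            if ld.r2(best, s) >= r2_threshold:
                continue
            kept.append(s)
        remaining = kept
    return selected


def ld_clump(
    result: pd.DataFrame,
    ld: LdPanel,
    sig_threshold: float = 0.05,
    indep_r2: float = 0.6,
    lead_r2: float = 0.1,
):
    """Independent significant SNPs and lead SNPs from a conjFDR table.

    ``result`` needs columns SNP, CHR, BP, conjfdr.  Returns
    ``(independent, leads, lead_of)`` where ``lead_of`` maps each
    independent SNP to its lead.  SNPs at exactly the r² threshold are
    pruned (treated as linked).
    """
    sig = result.loc[result["conjfdr"] < sig_threshold]
    independent = _greedy_prune(sig, ld, indep_r2)
    leads = _greedy_prune(sig.loc[sig["SNP"].isin(independent)], ld, lead_r2)
    lead_of: dict[str, str] = {}
    for snp in independent:
        if snp in leads:
            lead_of[snp] = snp
            continue
        best_lead, best_r2 = None, -1.0
        for lead in leads:
            r2 = ld.r2(lead, snp)
            if r2 > best_r2:
                best_lead, best_r2 = lead, r2
        lead_of[snp] = best_lead
    return independent, leads, lead_of


def define_loci(
    result: pd.DataFrame,
    ld: LdPanel,
    independent: list[str],
    leads: list[str],
    lead_of: dict[str, str],
    cand_threshold: float = 0.10,
    cand_r2: float = 0.6,
    merge_kb: int = 250,
) -> list[Locus]:
    """Candidate SNPs, per-lead locus spans, and 250-kb merging.

    Candidates = {conjFDR < cand_threshold with r² > cand_r2 to some
    independent significant SNP} ∪ the independent set.  Each lead's locus
    spans its candidates' positions; loci on the same chromosome whose
    spans are within ``merge_kb`` kb are merged and the merged lead is the
    member SNP with minimum conjFDR.
    """
    res = result.set_index("SNP")
    cand_pool = result.loc[result["conjfdr"] < cand_threshold, "SNP"].tolist()

    members: dict[str, set[str]] = {lead: set() for lead in leads}
    for snp in independent:
        members[lead_of[snp]].add(snp)
    for snp in cand_pool:
        for ind in independent:
            if snp == ind or ld.r2(snp, ind) > cand_r2:
                if snp != ind and res.at[snp, "CHR"] != res.at[ind, "CHR"]:
                    continue
                members[lead_of[ind]].add(snp)

    raw: list[Locus] = []
    for lead in leads:
        mem = sorted(members[lead])
        pos = res.loc[mem, "BP"].astype(int)
        raw.append(
            Locus(
                chrom=str(res.at[lead, "CHR"]),
                start=int(pos.min()),
                end=int(pos.max()),
                lead_snp=lead,
                lead_conjfdr=float(res.at[lead, "conjfdr"]),
                independent_snps=sorted(set(mem) & set(independent)),
                candidate_snps=mem,
            )
        )

    raw.sort(key=lambda L: (_chrom_order(L.chrom), L.start))
    merged: list[Locus] = []
    gap = merge_kb * 1000
    for loc in raw:
        if merged and merged[-1].chrom == loc.chrom and loc.start - merged[-1].end <= gap:
            prev = merged[-1]
            cand = sorted(set(prev.candidate_snps) | set(loc.candidate_snps))
            indep = sorted(set(prev.independent_snps) | set(loc.independent_snps))
            lead = prev.lead_snp if prev.lead_conjfdr <= loc.lead_conjfdr else loc.lead_snp
            merged[-1] = Locus(
                chrom=loc.chrom,
                start=min(prev.start, loc.start),
                end=max(prev.end, loc.end),
                lead_snp=lead,
                lead_conjfdr=min(prev.lead_conjfdr, loc.lead_conjfdr),
                independent_snps=indep,
                candidate_snps=cand,
            )
        else:
            merged.append(loc)
    return merged


def _chrom_order(c: str) -> int:
    s = str(c)
    return int(s) if s.isdigit() else 10_000 + sum(map(ord, s))


def _norm_chrom(c) -> str:
    s = str(c).strip()
    return s[3:] if s.lower().startswith("chr") else s


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    """Tabular locus summary (one row per merged locus)."""
    return pd.DataFrame(
        [
            {
                "locus_id": i + 1,
                "chrom": L.chrom,
                "start": L.start,
                "end": L.end,
                "lead_snp": L.lead_snp,
                "lead_conjfdr": L.lead_conjfdr,
                "n_independent": len(L.independent_snps),
                "n_candidates": len(L.candidate_snps),
            }
            for i, L in enumerate(loci)
        ]
    )


def positional_map(
    loci: list[Locus],
    genes: pd.DataFrame,
    snp_positions: pd.DataFrame,
    window_bp: int = 10_000,
    map_spans: bool = False,
) -> list[str]:
    """Map candidate SNPs (or whole locus spans) to genes by position.

    A gene (columns gene, chrom, start, end; 1-based inclusive) is
    reported iff some candidate SNP position lies in
    [start - window_bp, end + window_bp] — or, with ``map_spans``, iff the
    locus span intersects that window.  ``snp_positions`` needs columns
    SNP, CHR, BP.  Chromosome labels are normalized (chr1 == 1).  Returns
    a deduplicated sorted gene list.
    """
    g = genes.copy()
    g["_chrom"] = g["chrom"].map(_norm_chrom)
    if (genes["chrom"].astype(str) != g["_chrom"]).any():
        warnings.warn("chromosome labels normalized (chr prefix stripped)")
    pos_lookup = snp_positions.set_index("SNP")
    hits: set[str] = set()
    for L in loci:
        lchrom = _norm_chrom(L.chrom)
        sub = g.loc[g["_chrom"] == lchrom]
        if map_spans:
            sel = (sub["start"] - window_bp <= L.end) & (sub["end"] + window_bp >= L.start)
            hits.update(sub.loc[sel, "gene"])
            continue
        for snp in L.candidate_snps:
            if snp not in pos_lookup.index:
                continue
            bp = int(pos_lookup.at[snp, "BP"])
            sel = (sub["start"] - window_bp <= bp) & (sub["end"] + window_bp >= bp)
            hits.update(sub.loc[sel, "gene"])
    return sorted(hits)
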