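"""Functional prediction: miRNA-sponge sites and circular open reading frames.

Target scoring follows the Allen et al. plant penalty scheme: per aligned
position 0 for a Watson-Crick pair, 0.5 for a G:U wobble, 1 for a mismatch,
with penalties doubled in the seed-critical region (miRNA positions 2-13
from the 5' end). Sites with total penalty <= 4.0 are reported, the
conventional plant-target cutoff. Scanning is circular: the sequence is
extended by its first L-1 bases so junction-spanning sites are found.

ORF detection is likewise circular: all three frames of the sequence
concatenated ``max_wraps`` times are scanned from start offsets in the first
copy; an ATG with no in-frame stop across the allowed wraps is a rolling ORF
(rolling-circle translation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U pairs in DNA alphabet
STOPS = {"TAA", "TAG", "TGA"}


def _norm(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT/U characters: {sorted(bad)}")
    return seq


def score_target(
    mirna_seq: str, circ_window: str, return_alignment: bool = False
):
    """Allen-rule penalty of a candidate site (gap-free).

    The miRNA (5'->3') pairs antiparallel with the circRNA window (5'->3'):
    miRNA position i pairs with window position L-1-i. Positions 2-13 from
    the miRNA 5' end carry doubled penalties.
    """
    mirna = _norm(mirna_seq)
    window = _norm(circ_window)
    if len(mirna) != len(window):
        raise ValueError("window length must equal miRNA length in gap-free mode")
    penalty = 0.0
    marks = []
    L = len(mirna)
    for i in range(L):
        pair = (mirna[i], window[L - 1 - i])
        if pair in _WC:
            cost, mark = 0.0, "|"
        elif pair in _WOBBLE:
            cost, mark = 0.5, "o"
        else:
            cost, mark = 1.0, "."
        if 2 <= i + 1 <= 13:  # seed-critical region, 1-based from miRNA 5' end
            cost *= 2.0
        penalty += cost
        marks.append(mark)
    if return_alignment:
        return penalty, "".join(marks)
    return penalty


def find_targets(
    circ_seqs: dict[str, str],
    mirna_seqs: dict[str, str],
    cutoff: float = 4.0,
    circular: bool = True,
) -> pd.DataFrame:
    """Scan every circularized offset of every circRNA against every miRNA.

    Returns a hit table (circ_id, mirna_id, offset, score, alignment) with
    score <= cutoff; offsets are 0-based positions of the site's 5' end on
    the circRNA.
    """
    rows = []
    for cid, circ in circ_seqs.items():
        circ = _norm(circ)
        L = len(circ)
        for mid, mirna in mirna_seqs.items():
            mirna = _norm(mirna)
            m = len(mirna)
            if L < m:
                continue
            ext = circ + circ[: m - 1] if circular else circ
            n_offsets = L if circular else L - m + 1
            for off in range(n_offsets):
                score, aln = score_target(mirna, ext[off : off + m], return_alignment=True)
                if score <= cutoff:
                    rows.append(
                        {"circ_id": cid, "mirna_id": mid, "offset": off,
                         "score": score, "alignment": aln}
                    )
    return pd.DataFrame(rows, columns=["circ_id", "mirna_id", "offset", "score", "alignment"])


def summarize_target_bins(hits: pd.DataFrame) -> dict[str, int]:
    """Single-site vs multi-site circRNA bins (sites counted as distinct
    (miRNA, offset) hits) and the targeted-circRNA total."""
    if hits.empty:
        return {"single_site": 0, "multi_site": 0, "total": 0}
    sites = hits.groupby("circ_id").size()
    single = int((sites == 1).sum())
    multi = int((sites > 1).sum())
    return {"single_site": single, "multi_site": multi, "total": single + multi}


def targeted_mirna_fraction_by_class(
    hits: pd.DataFrame, class_sets: dict[str, set]
) -> pd.DataFrame:
    """Per circRNA class, the fraction of all targeted miRNAs hit by that
    class (the module-level sponge summary)."""
    all_targeted = set(hits["mirna_id"]) if len(hits) else set()
    rows = []
    for name, circ_set in class_sets.items():
        sub = hits.loc[hits["circ_id"].isin(circ_set)] if len(hits) else hits
        mirnas = set(sub["mirna_id"]) if len(sub) else set()
        frac = len(mirnas) / len(all_targeted) if all_targeted else np.nan
        rows.append({"class": name, "n_mirnas": len(mirnas), "fraction_of_targeted": frac})
    return pd.DataFrame(rows)


@dataclass
class OrfHit:
    circ_id: str
    start_offset: int  # 0-based on the circRNA
    length_nt: int  # start codon through stop codon inclusive
    spans_junction: bool
    rolling: bool


def find_circular_orfs(
    circ_seq: str,
    min_orf_nt: int = 63,
    max_wraps: int = 4,
    circ_id: str = "",
) -> list[OrfHit]:
    """All ORFs (ATG..stop) on the circularized sequence.

    Start offsets are scanned in the first copy of the sequence and read into
    ``max_wraps`` concatenated copies, so junction-spanning and rolling ORFs
    are found. A frame with an ATG but no stop across the wraps is reported
    rolling, with length max_wraps * L truncated to a codon multiple.
    """
    seq = _norm(circ_seq)
    L = len(seq)
    if L < 1:
        raise ValueError("empty sequence")
    ext = seq * max_wraps
    hits: list[OrfHit] = []
    for start in range(L):
        if ext[start : start + 3] != "ATG":
            continue
        length = None
        rolling = False
        pos = start
        while pos + 3 <= len(ext):
            if ext[pos : pos + 3] in STOPS:
                length = pos + 3 - start
                break
            pos += 3
        if length is None:
            rolling = True
            length = 3 * ((max_wraps * L - start) // 3)
        if length >= min_orf_nt:
            hits.append(
                OrfHit(circ_id, start, length, spans_junction=start + length > L,
                       rolling=rolling)
            )
    return hits


def orf_table(circ_seqs: dict[str, str], min_orf_nt: int = 63, max_wraps: int = 4) -> pd.DataFrame:
    rows = [
        vars(h)
        for cid, seq in circ_seqs.items()
        for h in find_circular_orfs(seq, min_orf_nt, max_wraps, circ_id=cid)
    ]
    return pd.DataFrame(
        rows, columns=["circ_id", "start_offset", "length_nt", "spans_junction", "rolling"]
    )


def coding_potential(
    orf_hits: pd.DataFrame,
    circ_ids: list[str],
    ires_flags: pd.Series | None = None,
) -> pd.Series:
    """Per-circRNA coding potential: has an ORF AND (when IRES annotation is
    supplied) an IRES; without IRES annotation this is ORF-only mode."""
    has_orf = pd.Series(False, index=pd.Index(circ_ids, name="circ_id"))
    if len(orf_hits):
        has_orf[has_orf.index.intersection(orf_hits["circ_id"].unique())] = True
    if ires_flags is None:
        return has_orf.rename("coding_potential")
    ires = pd.Series(ires_flags).reindex(has_orf.index).fillna(False).astype(bool)
    return (has_orf & ires).rename("coding_potential")


def coding_fraction_by_class(potential: pd.Series, class_sets: dict[str, set]) -> pd.DataFrame:
    rows = []
    for name, circ_set in class_sets.items():
        sub = potential.loc[potential.index.intersection(pd.Index(list(circ_set)))]
        rows.append(
            {"class": name, "n": len(sub),
             "fraction_coding": float(sub.mean()) if len(sub) else np.nan}
        )
    return pd.DataFrame(rows)
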