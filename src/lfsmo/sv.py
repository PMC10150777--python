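"""Ensemble SV consensus and CNV intersection.

Two independent SV callers rarely agree on exact breakpoints, so
consensus uses a size-tiered breakpoint tolerance: 100 bp for events up
to 10 kb, 1 kb up to 50 kb, 10 kb beyond.  Consensus events are then
screened against a panel of normals (recurrent technical artifacts), an
annotation score and population SV databases.  CNV calls from two
read-depth callers are intersected and cleaned of repetitive /
low-complexity regions.

Callset tables are BED-like DataFrames with 1-based inclusive ``start``
and ``end`` columns plus ``svtype``/``state``, ``caller`` and
``sample_id`` (``annot_score`` and ``popdb_hit`` for annotated SVs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "breakpoint_tolerance",
    "merge_callsets",
    "filter_pon",
    "filter_annotation",
    "intersect_cnv",
]

_INFEASIBLE = 10.0**15


def breakpoint_tolerance(sv_length: float) -> int:
    """Maximum breakpoint distance allowed for a consensus match.

    <=10 kb -> 100 bp; (10 kb, 50 kb] -> 1 kb; >50 kb -> 10 kb.  At the
    ambiguous 10 kb boundary the stricter tolerance wins.
    """
    if sv_length <= 0:
        raise ValueError(f"SV length must be positive, got {sv_length}")
    if sv_length <= 10_000:
        return 100
    if sv_length <= 50_000:
        return 1_000
    return 10_000


def _pair_delta(xa, xb):
    """Total breakpoint delta if the pair is a feasible match, else None."""
    if xa["chrom"] != xb["chrom"] or xa["svtype"] != xb["svtype"]:
        return None
    len_a = xa["end"] - xa["start"] + 1
    len_b = xb["end"] - xb["start"] + 1
    tol = breakpoint_tolerance((len_a + len_b) / 2.0)
    ds = abs(int(xa["start"]) - int(xb["start"]))
    de = abs(int(xa["end"]) - int(xb["end"]))
    if ds <= tol and de <= tol:
        return ds + de
    return None


def merge_callsets(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Consensus of two single-sample callsets by optimal breakpoint matching.

    A pair matches iff it shares chromosome and SV type and both
    breakpoints lie within the size-tiered tolerance (computed at the
    mean of the two call lengths).  Each call joins at most one
    consensus event; among all maximum-cardinality matchings the one
    with the smallest total breakpoint delta is chosen (solved as an
    assignment problem).  The merged interval takes the midpoint of the
    matched breakpoints, rounded down.

    Returns a DataFrame with one row per consensus event: merged
    coordinates, svtype, sample, per-caller source coordinates and
    breakpoint deltas, and a ``filter_status`` column initialized to
    ``pass``.
    """
    for df, name in ((a, "a"), (b, "b")):
        if df["sample_id"].nunique() > 1:
            raise ValueError(f"callset {name} mixes samples")
    if len(a) and len(b):
        sa, sb = a["sample_id"].iloc[0], b["sample_id"].iloc[0]
        if sa != sb:
            raise ValueError(f"callsets are from different samples: {sa!r} vs {sb!r}")
    a = a.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    b = b.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    if not len(a) or not len(b):
        return _empty_consensus()

    cost = np.full((len(a), len(b)), _INFEASIBLE)
    rec_a = a.to_dict("records")
    rec_b = b.to_dict("records")
    for i, xa in enumerate(rec_a):
        for j, xb in enumerate(rec_b):
            d = _pair_delta(xa, xb)
            if d is not None:
                cost[i, j] = d
    n = max(len(a), len(b))
    padded = np.full((n, n), _INFEASIBLE)
    padded[: len(a), : len(b)] = cost
    rows, cols = linear_sum_assignment(padded)

    out = []
    for i, j in zip(rows, cols):
        if i >= len(a) or j >= len(b) or padded[i, j] >= _INFEASIBLE:
            continue
        xa, xb = rec_a[i], rec_b[j]
        out.append(
            {
                "chrom": xa["chrom"],
                "start": (int(xa["start"]) + int(xb["start"])) // 2,
                "end": (int(xa["end"]) + int(xb["end"])) // 2,
                "svtype": xa["svtype"],
                "sample_id": xa.get("sample_id"),
                "caller_a": xa.get("caller", "a"),
                "start_a": int(xa["start"]),
                "end_a": int(xa["end"]),
                "caller_b": xb.get("caller", "b"),
                "start_b": int(xb["start"]),
                "end_b": int(xb["end"]),
                "delta_start": abs(int(xa["start"]) - int(xb["start"])),
                "delta_end": abs(int(xa["end"]) - int(xb["end"])),
                "annot_score": _combine_scores(xa, xb),
                "popdb_hit": bool(xa.get("popdb_hit", False) or xb.get("popdb_hit", False)),
                "filter_status": "pass",
            }
        )
    cons = pd.DataFrame(out, columns=_CONSENSUS_COLUMNS)
    return cons.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


_CONSENSUS_COLUMNS = [
    "chrom", "start", "end", "svtype", "sample_id",
    "caller_a", "start_a", "end_a", "caller_b", "start_b", "end_b",
    "delta_start", "delta_end", "annot_score", "popdb_hit", "filter_status",
]


def _empty_consensus() -> pd.DataFrame:
    return pd.DataFrame(columns=_CONSENSUS_COLUMNS)


def _combine_scores(xa, xb):
    scores = [x.get("annot_score") for x in (xa, xb)]
    scores = [s for s in scores if s is not None and not pd.isna(s)]
    return min(scores) if scores else np.nan


def filter_pon(
    consensus: pd.DataFrame,
    pon: dict[str, pd.DataFrame] | list[pd.DataFrame],
    min_support: int = 3,
) -> pd.DataFrame:
    """Flag consensus events recurring in >= ``min_support`` control genomes.

    A control supports an event when it contains a call matching under
    the same size-tiered tolerance rule used for consensus.  Flagged
    events get ``filter_status = "pon"``; nothing is deleted.
    """
    if isinstance(pon, dict):
        callsets = list(pon.values())
    else:
        callsets = list(pon)
    out = consensus.copy()
    if not len(out) or not callsets:
        return out
    support = np.zeros(len(out), dtype=int)
    recs = out.to_dict("records")
    for ctrl in callsets:
        ctrl_recs = ctrl.to_dict("records")
        for i, ev in enumerate(recs):
            if any(_pair_delta(ev, c) is not None for c in ctrl_recs):
                support[i] += 1
    flag = (support >= min_support) & (out["filter_status"] == "pass")
    out.loc[flag, "filter_status"] = "pon"
    out["pon_support"] = support
    return out


def filter_annotation(
    consensus: pd.DataFrame,
    min_score: int = 3,
    missing_score_fails: bool = True,
) -> pd.DataFrame:
    """Flag events with a low annotation score or a population-database hit.

    ``filter_status`` becomes ``annot_score`` when the score is below
    ``min_score`` (missing scores fail by default) and ``popdb`` when the
    event is present in public non-cancer SV databases.  Only events
    still at ``pass`` are re-flagged, keeping earlier filter provenance.
    """
    out = consensus.copy()
    if not len(out):
        return out
    score = pd.to_numeric(out["annot_score"], errors="coerce")
    low = score < min_score
    if missing_score_fails:
        low = low | score.isna()
    passing = out["filter_status"] == "pass"
    out.loc[passing & low, "filter_status"] = "annot_score"
    passing = out["filter_status"] == "pass"
    out.loc[passing & out["popdb_hit"].astype(bool), "filter_status"] = "popdb"
    return out


# ---------------------------------------------------------------------------
# CNV


def _normalize_intervals(df: pd.DataFrame) -> list[tuple[int, int]]:
    """Sorted, merged (start, end) 1-based inclusive intervals."""
    ivs = sorted((int(s), int(e)) for s, e in zip(df["start"], df["end"]))
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _intersect_lists(xs, ys):
    out = []
    i = j = 0
    while i < len(xs) and j < len(ys):
        s = max(xs[i][0], ys[j][0])
        e = min(xs[i][1], ys[j][1])
        if s <= e:
            out.append((s, e))
        if xs[i][1] < ys[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract_lists(xs, ys):
    out = []
    for s, e in xs:
        segs = [(s, e)]
        for ys_, ye in ys:
            nxt = []
            for cs, ce in segs:
                if ye < cs or ys_ > ce:
                    nxt.append((cs, ce))
                    continue
                if cs < ys_:
                    nxt.append((cs, ys_ - 1))
                if ye < ce:
                    nxt.append((ye + 1, ce))
            segs = nxt
        out.extend(segs)
    return out


def intersect_cnv(
    a: pd.DataFrame,
    b: pd.DataFrame,
    exclusion: pd.DataFrame | None = None,
    min_length: int = 1000,
) -> pd.DataFrame:
    """Regions called by both CNV callers with matching copy state.

    The exclusion list (repetitive / low-complexity regions) is
    subtracted from every intersection, and residual fragments shorter
    than ``min_length`` are dropped.  Commutative and idempotent.
    """
    for df in (a, b):
        if len(df) and (df["end"] < df["start"]).any():
            raise ValueError("malformed CNV interval: end < start")
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if exclusion is not None and len(exclusion):
        for chrom, grp in exclusion.groupby("chrom"):
            excl_by_chrom[chrom] = _normalize_intervals(grp)
    rows = []
    keys_a = a.groupby(["sample_id", "chrom", "state"]) if len(a) else []
    b_groups = (
        {k: g for k, g in b.groupby(["sample_id", "chrom", "state"])} if len(b) else {}
    )
    for key, ga in keys_a:
        gb = b_groups.get(key)
        if gb is None:
            continue
        sample, chrom, state = key
        inter = _intersect_lists(_normalize_intervals(ga), _normalize_intervals(gb))
        inter = _subtract_lists(inter, excl_by_chrom.get(chrom, []))
        for s, e in inter:
            if e - s + 1 >= min_length:
                rows.append(
                    {"chrom": chrom, "start": s, "end": e, "state": state,
                     "sample_id": sample}
                )
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "state", "sample_id"])
    return out.sort_values(["sample_id", "chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )
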