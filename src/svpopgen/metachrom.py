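"""Meta-chromosome positional enrichment of SVs.

Every chromosome arm is rescaled to half of a unit "meta-chromosome": the
p-arm maps onto [0, 0.5] (telomere → centromere) and the q-arm onto
[0.5, 1.0] (centromere → telomere). SVs (located by interval midpoint,
insertions by insertion point) are counted in fixed-width source windows
(100 kb by default), the windows' counts are averaged — unweighted over
arms — into meta-coordinate bins, divided by the class mean so every
profile has mean enrichment 1, and smoothed with a centered rolling mean.

Windows are labelled T (within 0.10 of either telomere), C (within 0.10 of
the centromere at 0.5) or I (interstitial); for each SV class × positional
class, a two-sided t-test compares that stratum's window enrichments with
the remaining windows, Bonferroni-adjusted over all comparisons run.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import rolling_mean
from .sv_io import SVRecord

log = logging.getLogger(__name__)

TEL_FRACTION = 0.10
CEN_FRACTION = 0.10


def load_arm_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "arm", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"arm map needs columns {sorted(required)}")
    return df


def normalize_position(chrom: str, pos: int, arm_map: pd.DataFrame) -> float | None:
    """Meta coordinate of a genomic position; None inside a centromere gap.

    p-ter = 0, centromere = 0.5, q-ter = 1.
    """
    arms = arm_map[arm_map["chrom"] == chrom]
    if not len(arms):
        raise ValueError(f"chromosome {chrom!r} absent from arm map")
    for _, arm in arms.iterrows():
        if arm["start"] <= pos < arm["end"]:
            frac = (pos - arm["start"]) / (arm["end"] - arm["start"])
            if arm["arm"] == "p":
                return 0.5 * frac
            return 0.5 + 0.5 * frac
    return None


def positional_class(meta: float, tel_fraction: float = TEL_FRACTION,
                     cen_fraction: float = CEN_FRACTION) -> str:
    if meta <= tel_fraction or meta >= 1.0 - tel_fraction:
        return "T"
    if abs(meta - 0.5) <= cen_fraction:
        return "C"
    return "I"


@dataclass
class MetaChromosomeProfile:
    svtype: str
    windows: pd.DataFrame  # meta, enrichment, smoothed, positional_class
    n_svs: int
    n_excluded: int


def profile_enrichment(svs: list[SVRecord], arm_map: pd.DataFrame,
                       window: int = 100_000, smoothing_window: int = 11,
                       n_meta_bins: int = 100) -> dict[str, MetaChromosomeProfile]:
    """Per-class enrichment along the meta-chromosome.

    Source 100-kb windows are assigned a meta coordinate (window center) and
    averaged into ``n_meta_bins`` equal meta bins; per-class enrichment is
    the bin's mean count per source window divided by the class average, so
    the profile mean is 1 by construction (restored after smoothing, whose
    truncated edges would otherwise perturb it). Classes with zero usable
    SVs are omitted with a warning.
    """
    # source windows: one row per (arm, window) with its meta bin
    win_rows = []
    for _, arm in arm_map.iterrows():
        for wstart in range(int(arm["start"]), int(arm["end"]), window):
            wend = min(wstart + window, int(arm["end"]))
            center = (wstart + wend) // 2
            meta = normalize_position(arm["chrom"], center, arm_map)
            if meta is None:
                continue
            win_rows.append({"chrom": arm["chrom"], "start": wstart, "end": wend,
                             "meta": meta})
    windows_df = pd.DataFrame(win_rows)
    edges = np.linspace(0, 1, n_meta_bins + 1)
    windows_df["bin"] = np.clip(
        np.digitize(windows_df["meta"], edges) - 1, 0, n_meta_bins - 1)

    profiles: dict[str, MetaChromosomeProfile] = {}
    by_type: dict[str, list[SVRecord]] = {}
    for r in svs:
        if r.is_bnd:
            continue
        by_type.setdefault(r.svtype, []).append(r)

    # vectorized window assignment: windows are contiguous within each arm
    arm_rows = [(str(a["chrom"]), int(a["start"]), int(a["end"])) for _, a in arm_map.iterrows()]
    win_offset = {}
    offset = 0
    for chrom, astart, aend in arm_rows:
        n_win = int(np.ceil((aend - astart) / window))
        win_offset[(chrom, astart)] = (offset, n_win)
        offset += n_win
    assert offset == len(windows_df)

    for svtype, recs in sorted(by_type.items()):
        counts = np.zeros(len(windows_df))
        n_excluded = 0
        used = 0
        pos_by_chrom: dict[str, list[int]] = {}
        for r in recs:
            pos = r.start if r.svtype == "INS" else r.midpoint
            pos_by_chrom.setdefault(r.chrom, []).append(pos)
        for chrom, astart, aend in arm_rows:
            positions = np.asarray(pos_by_chrom.get(chrom, []), dtype=int)
            if not len(positions):
                continue
            inside = (positions >= astart) & (positions < aend)
            idx = (positions[inside] - astart) // window
            off, n_win = win_offset[(chrom, astart)]
            np.add.at(counts, off + idx, 1)
            used += int(inside.sum())
        n_excluded = len(recs) - used
        if used == 0:
            log.warning("class %s has no SVs on mapped arms; profile omitted", svtype)
            continue
        wdf = windows_df.copy()
        wdf["count"] = counts
        binned = wdf.groupby("bin").agg(
            meta=("meta", "mean"), n_windows=("count", "size"),
            total=("count", "sum")).reset_index()
        rate = binned["total"] / binned["n_windows"]
        enrichment = rate / rate.mean()
        smoothed = rolling_mean(enrichment.to_numpy(), smoothing_window)
        smoothed = smoothed / smoothed.mean()
        out = pd.DataFrame({
            "bin": binned["bin"], "meta": binned["meta"],
            "n_windows": binned["n_windows"],
            "enrichment": enrichment,
            "smoothed": smoothed,
        })
        out["positional_class"] = [positional_class(m) for m in out["meta"]]
        profiles[svtype] = MetaChromosomeProfile(svtype, out, used, n_excluded)
    return profiles


def positional_tests(profiles: dict[str, MetaChromosomeProfile],
                     alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided t-tests of each positional stratum vs the rest, per class.

    The Bonferroni threshold is alpha/k for the k = classes × 3 comparisons
    actually run (7 SV classes × 3 positions gives the 0.05/21 = 2.38e-3
    threshold); strata with fewer than 2 windows are reported as NA.
    """
    rows = []
    for svtype, prof in sorted(profiles.items()):
        for pos_class in ("C", "I", "T"):
            mask = prof.windows["positional_class"] == pos_class
            inside = prof.windows.loc[mask, "enrichment"].to_numpy()
            outside = prof.windows.loc[~mask, "enrichment"].to_numpy()
            if len(inside) < 2 or len(outside) < 2:
                rows.append({"svtype": svtype, "positional_class": pos_class,
                             "n_windows": int(mask.sum()), "t": np.nan, "p": np.nan})
                continue
            t, p = stats.ttest_ind(inside, outside, equal_var=False)
            rows.append({"svtype": svtype, "positional_class": pos_class,
                         "n_windows": int(mask.sum()),
                         "mean_enrichment": float(inside.mean()),
                         "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    k = int(df["p"].notna().sum())
    df["bonferroni_k"] = k
    df["adjusted_threshold"] = alpha / k if k else np.nan
    df["significant"] = df["p"] < (alpha / k if k else np.nan)
    return df


def bonferroni_threshold(alpha: float, k: int) -> float:
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k
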