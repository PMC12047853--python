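"""Aggregation of pipeline outputs into the study-style result surfaces.

Per-source post/user counts, monthly message volume with a November–March
seasonality index, the single-topic distribution table, cohort indicators
(posts per user, gender shares, age distribution) and the quality-of-life
impact tables under both of their percentage conventions.

Rounding is half-up throughout: 2 decimals for source/topic-style shares,
integer percent for the QoL shares — every emitted percentage recomputes
exactly from its printed count and denominator.
"""

from __future__ import annotations

import logging
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .lexicons import QOL_CATEGORIES
from .topic_model import UNASSIGNED

logger = logging.getLogger(__name__)

WINTER_MONTHS = (11, 12, 1, 2, 3)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: float, denominator: float, ndigits: int = 2) -> float:
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * count / denominator, ndigits)


# -- Table-1 style: sources ------------------------------------------------

def source_table(posts: pd.DataFrame,
                 other_threshold: int = 0,
                 other_label: str = "Other sites") -> pd.DataFrame:
    """Per-source post and distinct-user counts, descending by posts.

    Sources with fewer than `other_threshold` posts are merged into a
    single aggregate row; a totals row closes the table.
    """
    grp = posts.groupby("source").agg(
        posts=("id", "size"), users=("author", "nunique"))
    small = grp.index[grp["posts"] < other_threshold]
    if len(small) > 0:
        sub = posts[posts["source"].isin(small)]
        merged = pd.DataFrame(
            {"posts": [len(sub)], "users": [sub["author"].nunique()]},
            index=pd.Index([other_label], name="source"))
        grp = pd.concat([grp.drop(index=small), merged])
    grp = grp.sort_values(["posts", "users"], ascending=False,
                          kind="mergesort")
    total = pd.DataFrame({"posts": [grp["posts"].sum()],
                          "users": [posts["author"].nunique()]},
                         index=pd.Index(["Total"], name="source"))
    return pd.concat([grp, total]).reset_index()


# -- Fig-4 style: monthly volume and seasonality ---------------------------

def monthly_volume(posts: pd.DataFrame,
                   window: tuple[str, str] | None = None) -> pd.DataFrame:
    """Message counts per calendar month over a dense (gap-free) calendar.

    Posts outside an explicit window are excluded with a logged count.
    """
    ts = pd.to_datetime(posts["timestamp"])
    periods = ts.dt.to_period("M")
    if window is not None:
        lo, hi = pd.Period(window[0], "M"), pd.Period(window[1], "M")
        mask = (periods >= lo) & (periods <= hi)
        n_out = int((~mask).sum())
        if n_out:
            logger.info("monthly_volume: excluded %d out-of-window posts",
                        n_out)
        periods = periods[mask]
    else:
        lo, hi = periods.min(), periods.max()
    calendar = pd.period_range(lo, hi, freq="M")
    counts = periods.value_counts().reindex(calendar, fill_value=0)
    return pd.DataFrame({"month": calendar.astype(str),
                         "count": counts.to_numpy()})


def seasonality_index(volume: pd.DataFrame) -> float:
    """mean monthly volume over Nov–Mar divided by mean over Apr–Oct."""
    months = pd.PeriodIndex(volume["month"], freq="M").month
    winter = volume.loc[np.isin(months, WINTER_MONTHS), "count"]
    summer = volume.loc[~np.isin(months, WINTER_MONTHS), "count"]
    if len(summer) == 0 or summer.mean() == 0:
        return float("nan")
    return float(winter.mean() / summer.mean())


# -- Table-2 style: topics -------------------------------------------------

def topic_table(assignments: np.ndarray | list[int],
                labels: dict[int, str] | None = None) -> pd.DataFrame:
    """Count and 2-decimal percentage per topic, descending.

    Unassigned messages (sentinel) are reported in an attribute row count
    and excluded from the denominator.
    """
    arr = np.asarray(assignments)
    assigned = arr[arr != UNASSIGNED]
    denom = len(assigned)
    topics, counts = np.unique(assigned, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    rows = []
    for t, c in zip(topics[order], counts[order]):
        name = labels.get(int(t), f"topic {t}") if labels else f"topic {t}"
        rows.append({"topic": name, "count": int(c),
                     "percent": percentage(int(c), denom, 2),
                     "denominator": denom})
    out = pd.DataFrame(rows,
                       columns=["topic", "count", "percent", "denominator"])
    out.attrs["n_unassigned"] = int((arr == UNASSIGNED).sum())
    return out


def counts_table(counts: dict[str, int], denominator: int | None = None,
                 ndigits: int = 2) -> pd.DataFrame:
    """Summary table from already-aggregated counts.

    The denominator defaults to the sum of the counts; passing it
    explicitly supports tables whose published denominator is not the
    column sum (e.g. when some rows of a partition are omitted).
    """
    if denominator is None:
        denominator = sum(counts.values())
    rows = [{"label": k, "count": int(v),
             "percent": percentage(v, denominator, ndigits),
             "denominator": denominator}
            for k, v in sorted(counts.items(), key=lambda kv: -kv[1])]
    return pd.DataFrame(rows)


# -- cohort indicators -----------------------------------------------------

def cohort_stats(posts: pd.DataFrame,
                 profiles: pd.DataFrame) -> dict:
    """Posts-per-user mean, gender shares over gender-determined users,
    and a decadal age histogram."""
    n_posts = len(posts)
    n_users = posts["author"].nunique()
    mean_ppu = round_half_up(n_posts / n_users, 2) if n_users else 0.0
    det = profiles[profiles["gender"].isin(["female", "male"])]
    n_det = len(det)
    n_female = int((det["gender"] == "female").sum())
    ages = profiles["age"].dropna().to_numpy(float)
    bins = np.arange(10, 101, 10)
    hist, _ = np.histogram(ages, bins=bins)
    return {
        "n_posts": n_posts,
        "n_users": n_users,
        "mean_posts_per_user": mean_ppu,
        "n_gender_determined": n_det,
        "n_female": n_female,
        "female_percent": percentage(n_female, n_det, 2),
        "male_percent": percentage(n_det - n_female, n_det, 2),
        "mean_age": float(np.mean(ages)) if len(ages) else float("nan"),
        "age_histogram": {f"{lo}-{lo + 9}": int(h)
                          for lo, h in zip(bins[:-1], hist)},
    }


# -- Table-3 style: QoL impacts --------------------------------------------

def qol_table(category_counts: dict[str, int],
              n_impact_messages: int) -> pd.DataFrame:
    """Both published QoL percentage conventions, denominators alongside.

    message_share_percent: share of impact-bearing messages carrying the
    category; mention_share_percent: share of all category mentions.
    Integer half-up rounding for both.
    """
    n_mentions = sum(category_counts.values())
    rows = []
    for c in QOL_CATEGORIES:
        n = int(category_counts.get(c, 0))
        rows.append({
            "category": c,
            "count": n,
            "message_share_percent": percentage(n, n_impact_messages, 0),
            "message_denominator": n_impact_messages,
            "mention_share_percent": percentage(n, n_mentions, 0),
            "mention_denominator": n_mentions,
        })
    return pd.DataFrame(rows).sort_values("count", ascending=False,
                                          kind="mergesort").reset_index(drop=True)


def audit_percentages(table: pd.DataFrame, count_col: str, percent_col: str,
                      denom_col: str, ndigits: int) -> bool:
    """True iff every percentage recomputes from its count and denominator."""
    for _, row in table.iterrows():
        if percentage(row[count_col], row[denom_col], ndigits) != row[percent_col]:
            return False
    return True
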