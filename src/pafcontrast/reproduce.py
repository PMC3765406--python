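"""Recompute every statistic derivable from the bundled published counts.

The raw genotypes behind the motivating study are not publicly depositable,
but its printed summary tables are enough to recompute the multiple-testing
threshold, the per-group binomial tail probabilities, the meta-level count
test, the direction sign test, and all literature-comparison aggregates.
This module loads the bundled counts fixture and reruns those computations
through the same functions the pipeline uses on synthetic data.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .group_enrichment import (
    Tail,
    bonferroni_threshold,
    direction_sign_test,
    group_binomial_test,
    meta_count_probability,
)

FIXTURE = "published_counts.json"


def load_published_counts() -> dict:
    with resources.files("pafcontrast").joinpath("data", FIXTURE).open(encoding="utf-8") as fh:
        return json.load(fh)


def comparison_table(entry: dict, bin_labels) -> pd.DataFrame:
    """Bin-range table (totals, differing, percent) from printed counts."""
    totals = np.asarray(entry["totals"], dtype=int)
    differing = np.asarray(entry["differing"], dtype=int)
    if (differing > totals).any():
        raise ValueError(f"{entry['name']}: differing exceeds totals")
    pct = np.where(totals > 0, 100.0 * differing / np.maximum(totals, 1), 0.0)
    return pd.DataFrame(
        [
            np.append(totals, totals.sum()),
            np.append(differing, differing.sum()),
            np.append(pct, 100.0 * differing.sum() / totals.sum()),
        ],
        index=["total_snps", "differing", "percent_of_total"],
        columns=list(bin_labels) + ["Total"],
    )


def reproduce_published_statistics(counts: dict | None = None) -> dict:
    """Statistics bundle recomputed from printed counts only.

    Returns the Bonferroni threshold, meta count-test probability, direction
    sign-test probability, per-group recomputed binomial probabilities, and
    the literature-comparison per-cohort and aggregate percentages.
    """
    counts = counts or load_published_counts()
    groups = counts["functional_groups"]
    base_rate = groups["base_rate"]

    group_rows = []
    for row in groups["rows"]:
        result = group_binomial_test(
            row["group"], row["total_snps"], row["differing"], base_rate,
            row["genes"], Tail.STRICT, Tail.INCLUSIVE,
        )
        group_rows.append(
            {
                "group": row["group"],
                "total_snps": row["total_snps"],
                "differing": row["differing"],
                "genes": row["genes"],
                "probability": result.probability,
                "direction": result.direction.value,
                "published_direction": row["direction"],
            }
        )
    group_frame = pd.DataFrame(group_rows)

    tables = {
        entry["name"]: comparison_table(entry, counts["bin_labels"])
        for entry in counts["literature_comparisons"]
    }
    european = [e for e in counts["literature_comparisons"] if e["european"]]
    agg_total = sum(sum(e["totals"]) for e in european)
    agg_diff = sum(sum(e["differing"]) for e in european)

    return {
        "bonferroni_threshold": bonferroni_threshold(groups["alpha"], groups["n_groups"]),
        "meta_probability": meta_count_probability(
            groups["n_significant"], groups["n_groups"], groups["alpha"], Tail.STRICT
        ),
        "sign_test_probability": direction_sign_test(
            groups["n_more"], groups["n_less"], Tail.INCLUSIVE
        ),
        "n_groups": groups["n_groups"],
        "n_significant": groups["n_significant"],
        "group_table": group_frame,
        "comparison_tables": tables,
        "per_cohort_percent_differing": {
            e["name"]: 100.0 * sum(e["differing"]) / sum(e["totals"])
            for e in counts["literature_comparisons"]
        },
        "european_aggregate_total": agg_total,
        "european_aggregate_differing": agg_diff,
        "european_aggregate_percent": 100.0 * agg_diff / agg_total,
    }
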