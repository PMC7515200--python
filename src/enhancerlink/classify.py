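"""Differential-activity classification of enhancer probes.

Each atlas probe is classified from its beta values in normal vs tumor
samples (low beta at an enhancer implies an open, active element):

* unmethylated  - constitutively active: low mean beta in both groups
* methylated    - constitutively inactive: high mean beta in both groups
* hypermethylated - active in normal, silenced in a tumor subset: low mean
  in normals, with at least ``min_tumor_fraction`` of tumors above
  ``tumor_hyper_cutoff``
* hypomethylated  - inactive in normal, activated in a tumor subset: high
  mean in normals, with at least ``min_tumor_fraction`` of tumors below
  ``tumor_hypo_cutoff``
* unclassified  - anything else, including probes with too many missing
  betas

The differential classes are evaluated before the constitutive ones: a
probe with a bimodal tumor distribution can satisfy a constitutive mean
rule and a differential subset rule simultaneously, and the differential
call is the informative one.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import ClinicalTable, MethylationMatrix, ValidationError

CLASSES = (
    "methylated",
    "unmethylated",
    "hypermethylated",
    "hypomethylated",
    "unclassified",
)


@dataclass
class ClassificationCutoffs:
    """Beta cutoffs for the four-way probe classification.

    The qualitative rules are fixed; the numeric cutoffs are configuration
    and are echoed into every output header.
    """

    unmeth_cutoff: float = 0.2
    meth_cutoff: float = 0.8
    tumor_hyper_cutoff: float = 0.6
    tumor_hypo_cutoff: float = 0.4
    min_tumor_fraction: float = 0.05
    max_missing_fraction: float = 0.2

    def __post_init__(self):
        ok = (
            0 <= self.unmeth_cutoff < self.tumor_hypo_cutoff
            <= self.tumor_hyper_cutoff < self.meth_cutoff <= 1
        )
        if not ok:
            raise ValidationError(
                "cutoffs must satisfy 0 <= unmeth < tumor_hypo <= tumor_hyper "
                "< meth <= 1"
            )
        if not (0 < self.min_tumor_fraction <= 1):
            raise ValidationError("min_tumor_fraction must be in (0, 1]")
        if not (0 <= self.max_missing_fraction <= 1):
            raise ValidationError("max_missing_fraction must be in [0, 1]")


def classify_probes(
    beta: MethylationMatrix,
    clinical: ClinicalTable,
    cutoffs: ClassificationCutoffs | None = None,
) -> pd.DataFrame:
    """Classify every probe row of ``beta``.

    Returns a DataFrame indexed by probe_id with columns class,
    mean_normal, mean_tumor, n_missing.  Missing betas are excluded from
    all means and fractions; a probe missing more than
    ``max_missing_fraction`` of its values is unclassified.
    """
    cutoffs = cutoffs or ClassificationCutoffs()
    normal = [s for s in clinical.normal_samples if s in beta.beta.columns]
    tumor = [s for s in clinical.tumor_samples if s in beta.beta.columns]
    if not normal:
        raise ValidationError("no normal samples present in the beta matrix")
    if not tumor:
        raise ValidationError("no tumor samples present in the beta matrix")

    bn = beta.beta[normal].to_numpy(float)
    bt = beta.beta[tumor].to_numpy(float)
    n_total = bn.shape[1] + bt.shape[1]

    with np.errstate(invalid="ignore"):
        mean_n = np.nanmean(bn, axis=1)
        mean_t = np.nanmean(bt, axis=1)
    n_missing = np.isnan(bn).sum(axis=1) + np.isnan(bt).sum(axis=1)
    n_t_obs = (~np.isnan(bt)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac_hyper = np.nansum(bt > cutoffs.tumor_hyper_cutoff, axis=1) / np.maximum(
            n_t_obs, 1
        )
        frac_hypo = np.nansum(bt < cutoffs.tumor_hypo_cutoff, axis=1) / np.maximum(
            n_t_obs, 1
        )

    cls = np.full(len(mean_n), "unclassified", dtype=object)
    usable = (n_missing / n_total <= cutoffs.max_missing_fraction) & (n_t_obs > 0)
    usable &= ~np.isnan(mean_n) & ~np.isnan(mean_t)

    hyper = usable & (mean_n < cutoffs.unmeth_cutoff) & (
        frac_hyper >= cutoffs.min_tumor_fraction
    )
    hypo = usable & (mean_n > cutoffs.meth_cutoff) & (
        frac_hypo >= cutoffs.min_tumor_fraction
    )
    unmeth = usable & (mean_n < cutoffs.unmeth_cutoff) & (
        mean_t < cutoffs.unmeth_cutoff
    )
    meth = usable & (mean_n > cutoffs.meth_cutoff) & (mean_t > cutoffs.meth_cutoff)

    # differential calls take precedence over constitutive ones
    cls[unmeth] = "unmethylated"
    cls[meth] = "methylated"
    cls[hyper] = "hypermethylated"
    cls[hypo] = "hypomethylated"

    return pd.DataFrame(
        {
            "class": cls,
            "mean_normal": mean_n,
            "mean_tumor": mean_t,
            "n_missing": n_missing,
        },
        index=pd.Index(beta.probe_ids, name="probe_id"),
    )


def write_classification(
    table: pd.DataFrame, cutoffs: ClassificationCutoffs, path
) -> None:
    """Write the classification TSV with a config-echo header block."""
    with open(path, "w") as fh:
        for key, val in asdict(cutoffs).items():
            fh.write(f"# {key} = {val}\n")
        table.to_csv(fh, sep="\t", float_format="%.10g")


def class_counts(table: pd.DataFrame) -> pd.Series:
    """Probe counts per class in canonical order."""
    return table["class"].value_counts().reindex(CLASSES, fill_value=0)
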