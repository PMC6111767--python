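"""Bundled reference data.

``reference_cohort_metrics.csv`` carries the per-subject validation
metrics of the 12-dog home-recording study the method was validated on:
recording/resting durations and the accuracy of the rest prediction from
low movement alone (ESS), from head posture alone, and of the full LMR
recumbent-alert prediction together with its specificity and NPV.
"""

from importlib import resources

import pandas as pd


def reference_cohort() -> pd.DataFrame:
    """The 12-subject reference performance table as a DataFrame."""
    with resources.files(__package__).joinpath("reference_cohort_metrics.csv").open() as fh:
        return pd.read_csv(fh)
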