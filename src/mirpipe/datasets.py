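"""Bundled example datasets.

Two small plain-text tables ship with the package, both from published
deep-sequencing measurements of porcine backfat small-RNA libraries
(Large White, a lean breed, versus Meishan, a fatty Chinese breed):

* ``backfat_known_mirna_expression.tsv`` — per-miRNA read counts in the
  two libraries together with the normalized expression (transcripts
  per million), log2 fold change (MS over LW), p-value and significance
  label as printed in the original expression table.
* ``novel_precursors.tsv`` — five novel porcine hairpin precursor
  sequences with their annotated mature miRNAs and reported minimum
  free energies (kcal/mol).

These serve as worked-example inputs and as fixed points for checking
the normalization, fold-change and folding code against published
numbers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = resources.files(__name__.rsplit(".", 1)[0]) / "data"


def load_backfat_expression() -> pd.DataFrame:
    """Known-miRNA expression profile of the two backfat libraries.

    Columns: ``name, lw_count, ms_count, lw_ne, ms_ne, log2fc, pvalue,
    sig``.  ``lw_ne``/``ms_ne`` are normalized expressions (reads per
    million clean reads), ``log2fc`` is log2(MS/LW) of those, ``sig``
    is the published significance label (``**`` = |log2fc| > 1 and
    p < 0.01).
    """
    with resources.as_file(_DATA / "backfat_known_mirna_expression.tsv") as p:
        df = pd.read_csv(p, sep="\t", keep_default_na=False)
    df["sig"] = df["sig"].astype(str)
    return df


def load_novel_precursors() -> pd.DataFrame:
    """Five novel porcine pre-miRNA hairpins with reported MFEs.

    Columns: ``name, precursor, mature, reported_mfe`` (kcal/mol).
    Every mature is an exact substring of its precursor.
    """
    with resources.as_file(_DATA / "novel_precursors.tsv") as p:
        return pd.read_csv(p, sep="\t")
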