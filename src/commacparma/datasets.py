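"""Published reference data bundled for comparison and regression checks."""

from __future__ import annotations

import pandas as pd


def phyllosphere_comparison() -> pd.DataFrame:
    """Previously reported competition metrics for six phyllosphere strains
    co-cultured with the epiphyte *Pantoea eucalypti* 299R.

    Columns: metabolic resource overlap (``mro``), phylogenetic distance to
    Pe299R, the Chesson-style competitive-ability score measured for each
    strain (``competition_score``), growth-based interaction strengths from
    two community FBA frameworks (``optcom_moma``, ``optcom``, ``micom``),
    and the per-pair COMMA competition rate (``comma_score``: competed /
    overlapped metabolites).
    """
    rows = [
        # strain, mro, phylo_dist, competition_score, optcom_moma, optcom, micom, comma_score
        ("PkP19E3", 0.74, 0.41, 2.64, 0.66, 0.53, 0.26, 0.037),
        ("PssB728a", 0.69, 0.41, 3.03, 0.66, 0.53, 0.26, 0.036),
        ("MethL85", 0.67, 0.68, 0.92, 0.63, 0.50, 0.25, 0.038),
        ("SmFR1", 0.69, 0.62, 1.05, 0.64, 0.50, 0.25, 0.059),
        ("ArthL145", 0.77, 0.76, 2.41, 0.70, 0.50, 0.25, 0.040),
        ("RhodL225", 0.62, 0.76, 0.69, 0.50, 0.03, 0.27, 0.047),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "strain",
            "mro",
            "phylogenetic_distance",
            "competition_score",
            "optcom_moma",
            "optcom",
            "micom",
            "comma_score",
        ],
    ).set_index("strain")
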