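#!/usr/bin/env python
"""Build the eight stage-preset ground-truth trees (neonate, 21, 35 and
57 dpn; pulmonary artery and vein) and verify that their whole-lung
branching statistics equal the published triples.

Writes results/preset_statistics.csv and one SWC per tree under
results/preset_trees/.
"""

from pathlib import Path

import pandas as pd

from vascmorph.phantom import (available_presets, generate_preset_tree,
                               load_branching_table, stage_preset)
from vascmorph.treestats import summarize
from vascmorph.volio import write_segment_table, write_swc

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20240


def main() -> None:
    out_trees = RESULTS / "preset_trees"
    out_trees.mkdir(parents=True, exist_ok=True)
    published = load_branching_table()
    published = published[published["scope"] == "total"].set_index(
        ["stage", "vessel"])

    rows = []
    for i, (stage, vessel) in enumerate(available_presets()):
        tree = generate_preset_tree(stage_preset(stage, vessel),
                                    seed=SEED + i)
        st = summarize(tree, "total")
        ref = published.loc[(stage, vessel)]
        rows.append({
            "stage": stage, "vessel": vessel,
            "median_generation": st.median_generation,
            "maximum_generation": st.maximum_generation,
            "vessel_count": st.vessel_count,
            "published_median": float(ref["median_generation"]),
            "published_maximum": int(ref["maximum_generation"]),
            "published_count": int(ref["vessel_count"]),
        })
        label = "pulmonary_artery" if vessel == "PA" else "pulmonary_vein"
        write_swc(tree, out_trees / f"{stage}_{vessel}.swc", label)
        write_segment_table(tree, out_trees / f"{stage}_{vessel}_segments.csv")

    df = pd.DataFrame(rows)
    df["exact"] = (
        (df.median_generation == df.published_median)
        & (df.maximum_generation == df.published_maximum)
        & (df.vessel_count == df.published_count)
    )
    df.to_csv(RESULTS / "preset_statistics.csv", index=False)
    print(df.to_string(index=False))
    n_exact = int(df.exact.sum())
    print(f"\n{n_exact}/8 preset trees reproduce the published whole-lung "
          f"(median, maximum, count) triples exactly.")


if __name__ == "__main__":
    main()
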