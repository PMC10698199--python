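#!/usr/bin/env python
"""Spatial association of the network T maps with reference maps.

Treats each subregion's unthresholded per-parcel T values as a spatial
map, decodes it against a bank of synthetic behavioral term maps (keeping
correlations above 0.1), and tests its association with synthetic
receptor-density maps using Fisher-z partial correlations (gray-matter
proxy covariate) against autocorrelation-preserving permutation nulls,
FDR-corrected across maps.  One of the receptor maps is constructed to
genuinely covary with subregion 1's network so the test has a planted
positive.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hippoparc.assoc import (
    ReferenceMap,
    association_test,
    build_null,
    decode_terms,
    partial_spatial_correlation,
)
from hippoparc.covariance import fisher_z
from hippoparc.synth import generate_reference_maps

OUT = Path(__file__).resolve().parent.parent / "results"
N_PERM = 500


def t_map(subregion: int) -> ReferenceMap:
    nm = pd.read_csv(OUT / f"network_map_subregion{subregion}.tsv", sep="\t", index_col=0)
    return ReferenceMap(
        values=pd.Series(nm["T"].to_numpy(), index=pd.RangeIndex(1, len(nm) + 1)),
        name=f"subregion{subregion}_T",
    )


def main():
    rng = np.random.default_rng(50)
    subregions = sorted(
        int(p.stem.replace("network_map_subregion", ""))
        for p in OUT.glob("network_map_subregion*.tsv")
    )
    queries = {k: t_map(k) for k in subregions}
    n_regions = len(queries[subregions[0]].values)

    term_maps = generate_reference_maps(20, n_regions, smoothness=2, seed=51, family="term")
    decoded = []
    for k, q in queries.items():
        hits = decode_terms(q, term_maps, threshold=0.1)
        decoded.extend({"subregion": k, "term": t, "r": r} for t, r in hits)
        print(f"subregion {k}: {len(hits)} term maps with r > 0.1")
    pd.DataFrame(decoded).to_csv(OUT / "term_decoding.tsv", sep="\t", index=False)

    receptor_maps = generate_reference_maps(
        11, n_regions, smoothness=2, seed=52, family="receptor"
    )
    # planted positive: a receptor map that follows subregion 1's network
    q1 = queries[subregions[0]].values.to_numpy()
    planted = ReferenceMap(
        values=pd.Series(
            0.8 * (q1 - q1.mean()) / q1.std() + 0.6 * rng.standard_normal(n_regions),
            index=queries[subregions[0]].values.index,
        ),
        name="receptor_planted",
        family="receptor",
    )
    receptor_maps.append(planted)
    gm_proxy = generate_reference_maps(1, n_regions, smoothness=3, seed=53)[0]

    # per subregion: observed z of its T map with every receptor map, tested
    # against that map's autocorrelation-preserving permutation null (single
    # observed z -> permutation-tail p), FDR across the 12 maps
    nulls = {
        m.name: build_null(m, n_perm=N_PERM, mode="autocorr_preserving", seed=54)
        for m in receptor_maps
    }
    all_rows = []
    for k, q in queries.items():
        observed = {
            m.name: np.array([fisher_z(partial_spatial_correlation(q, m, gm_proxy))])
            for m in receptor_maps
        }
        null_z = {
            name: np.array(
                [fisher_z(partial_spatial_correlation(q, nm_, gm_proxy)) for nm_ in ens]
            )
            for name, ens in nulls.items()
        }
        res = association_test(observed, null_z)
        sig = res.table.index[res.table.significant].tolist()
        print(f"subregion {k}: significant receptor maps: {sig}")
        all_rows.append(res.table.assign(subregion=k))
    pd.concat(all_rows).to_csv(OUT / "receptor_association.tsv", sep="\t")


if __name__ == "__main__":
    main()
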