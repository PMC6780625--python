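"""Shared fixtures: one fully generated synthetic study reused across
test modules."""

from __future__ import annotations

import pytest

from ampminer import anchor, synthetic


@pytest.fixture(scope="session")
def study():
    """A complete small synthetic study with ground truth: 2 chromosomes,
    planted AMP homologs plus decoys, fragmentation, linkage map, and an
    anchoring run."""
    truth = synthetic.gen_genome(seed=11, n_chromosomes=2, chromosome_length=60_000)
    queries = synthetic.gen_queries(seed=11)
    cds, coords = synthetic.plant_amp_genes(
        truth, queries, n_genes=8, substitution_rate=0.05, decoy_genes=15, seed=11
    )
    synthetic.fragment_to_scaffolds(truth, 8, seed=11)
    marker_df, flanks = synthetic.gen_linkage_map(
        truth, markers_per_scaffold=3, flank=40, seed=11
    )
    markers = [
        anchor.Marker(r.marker_id, int(r.linkage_group), float(r.cM), flanks[r.flank_id])
        for r in marker_df.itertuples()
    ]
    result = anchor.anchor_pipeline(markers, truth.scaffolds)
    return {
        "truth": truth,
        "queries": queries,
        "cds": cds,
        "coords": coords,
        "marker_df": marker_df,
        "flanks": flanks,
        "markers": markers,
        "anchoring": result,
    }
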