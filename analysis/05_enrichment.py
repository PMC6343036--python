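"""Functional enrichment of recombined genes, and profile clustering.

For each simulated species: overlap the called events with the gene table,
run the Fisher/FDR enrichment, and store the signed profile. Profiles across
species are then clustered by matching-coefficient similarity and written as
a table plus a newick dendrogram.
"""
import pathlib

import pandas as pd

from hrscan import enrich

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    profiles = {}
    for spdir in sorted((RESULTS / "species").iterdir()):
        genes = pd.read_csv(spdir / "genes.tsv", sep="\t", comment="#")
        events = pd.read_csv(spdir / "events_called.tsv", sep="\t")
        if events.empty:
            continue
        ev = [
            {"strain": r.strain, "start": r.genome_start, "end": r.genome_end}
            for r in events.itertuples()
        ]
        hit = enrich.genes_in_events(ev, genes)
        table = enrich.fisher_enrichment(enrich.category_table(hit, genes))
        table.to_csv(spdir / "enrichment.tsv", sep="\t", index=False)
        profiles[spdir.name] = enrich.signed_profile(table)
    if len(profiles) >= 2:
        prof = pd.DataFrame(profiles).T.fillna(0).astype(int)
        prof.to_csv(RESULTS / "enrichment_profiles.tsv", sep="\t")
        _, order, newick, sim = enrich.cluster_profiles(prof)
        (RESULTS / "enrichment_dendrogram.nwk").write_text(newick + "\n")
        sim.to_csv(RESULTS / "enrichment_similarity.tsv", sep="\t")
        print("species order after average-linkage clustering:", order)
    print(f"enrichment written for {len(profiles)} species")


if __name__ == "__main__":
    main()
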