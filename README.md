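# nailseq

Calling **early replication initiation zones (ERIZs)** from
nucleoside-analog incorporation sequencing, and relating them to
transcription, chromatin, and replication timing.

`nailseq` is aimed at genomicists studying where DNA replication starts in
mammalian genomes. It implements the full analysis chain for two
complementary assays:

* **Dual-label (EdU/BrdU)** — cells at the G1/S transition are pulsed with a
  first label (EdU) and then a second (BrdU). Initiation centers are
  EdU-dominant, while forks that have moved on deposit BrdU on the flanks.
* **EdU/HU** — EdU incorporated slowly under hydroxyurea concentrates reads
  sharply at initiation sites over a very sparse background.

An ERIZ is an EdU/HU peak that also overlaps a dual-label peak: the
HU assay supplies resolution, the stress-free dual-label assay removes
HU-induced dormant-origin artifacts.

## The calling rules

With E and B the RPM-normalized first/second-label coverage in 5-kb bins,

```
ΔEB = E − B
```

bins with ΔEB > 0.3 seed a peak; seeds extend through contiguous bins with
ΔEB > 0; regions longer than 20 kb that fall inside broad EdU-enriched
islands (Poisson-significant 5-kb windows chained across ≤ 3-window gaps)
are kept, and peaks must reproduce in ≥ 2 biological replicates.

EdU/HU peaks come from a fixed-bin scan against a global Poisson rate
(1-kb bins, upper-tail p < 1e-5), a ≥ 400-fold enrichment filter against
the background density, merging of neighbor peaks closer than 10 kb,
a ≥ 10-kb size filter, and blacklist/chrY/chrM exclusion.

Downstream, the package quantifies the spatial logic of initiation:

* **Transcription context** — active/silent gene classes from nascent-RNA
  (GRO-seq) densities; non-transcribed regions (non-TRs) between two active
  genes inside A compartments; the per-region log2 ratio of replication
  read density in the non-TR versus its flanking gene bodies, with a
  Wilcoxon rank-sum comparison between conditions.
* **Epigenetic prediction** — 50-kb A-compartment windows labelled by ERIZ
  overlap; per-marker shuffle-calibrated log-odds occupancy scores; a
  class-balanced logistic regression whose coefficients rank markers as
  positive or negative predictors.
* **dCas9 barrier analysis** — sliding-bin RPK profiles around a
  transcription barrier, normalized by the chromosome's B-compartment
  background, and a Student's t-test of the 2-kb bins immediately upstream
  versus downstream of the site.

Because the original deep-sequencing inputs are far beyond desk scale, the
package ships a first-class **synthetic-data generator** that plants known
zones, genes, compartments and marker peaks with the assays' signal
structure, so that every stage can be exercised and scored end to end.

## Worked example

```bash
python examples/01_call_erizs.py
```

```
planted zones:        50
ERIZs called:         50  (non-ERIZ EdU/HU peaks: 0)
zone recall:          1.00
zone precision:       1.00
median zone Jaccard:  0.991
ERIZs in early-replicating domains: 100.0 %
```

Fifty zones were planted in non-transcribed A-compartment gaps of a
2 × 25 Mb synthetic genome; the full chain (two dual-label replicates →
reproducible E−B peaks; EdU/HU scan → 400-fold filter; intersection →
ERIZs) recovers every one with ~1-kb boundary accuracy, calls nothing
spurious, and the mean replication-timing value of every ERIZ exceeds the
0.5 early/late cut. The other examples print the transcription-context
statistic (median log2 non-TR/TR ≈ +9.5 for replication reads vs ≈ 0 for a
uniform control), the predictor's coefficient table, and the barrier test
(upstream RPK ratio ≈ 5 vs downstream ≈ 0.9, p < 0.001).

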