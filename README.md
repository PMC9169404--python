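# circtrans

Translation-potential analysis for circular RNAs (circRNAs).

circRNAs are covalently closed RNA loops produced by back-splicing. They
lack a 5' cap, so any translation must initiate cap-independently —
through an internal ribosome entry site (IRES) or an m6A modification —
and the reading frame behaves unusually on a circle: when the length `L`
is divisible by 3 the frame is stable under wraparound, but when it is
not, stepping 3 nt around the circle visits *every* position before
closing after `3L` nt. `circtrans` implements the computational
consequences of this geometry:

- **ORF prediction** on circular sequences, including junction-spanning
  ORFs (up to `L` or `3L` nt depending on `L mod 3`), *infinite* ORFs
  (a reading orbit with a start codon and no stop, supporting
  rolling-circle translation of a repeating peptide with repeat unit
  `L` or `3L` nt, reported as "`<repeat> × n`"), the farthest-start rule with
  in-frame inner starts, and exact parity with a linear 3-frame finder
  on junction-free calls;
- **IRES prediction**: 174-nt sliding windows every 20 nt (154-nt
  overlap), global kmer frequencies (k = 1..4, count / length), and a
  gradient-boosted tree classifier (eta 0.03, max_depth 5,
  scale_pos_weight 8.78, subsample 0.9, colsample_bytree 0.5,
  min_child_weight 19) exposed as a scikit-learn estimator; positive
  fragments are assigned to ORFs by nearest-upstream circular distance;
- **m6A motif scanning**: all DRACH/RRACH pentamers (D = A/G/U,
  R = G/A, H = A/C/U) with the methylated A at offset +2, wrapping
  across the back-splice junction, plus intersection with a pre-lifted
  known-site table;
- **conserved ("homeotic") circRNA pairing** across species: same gene,
  identical length, global-alignment identity strictly > 80%.

Everything is available both as a library and as a `circtrans` CLI
(`orf`, `ires-train`, `ires-predict`, `m6a`, `conserve`, `report`,
`fixtures`) suitable for pipeline embedding; all outputs are
byte-deterministic for a fixed `--seed`.

## Worked example

```python
from circtrans import CircularSequence, find_orfs, scan_motifs

circ = CircularSequence("demo", "ATGGGACT" + "GGC" * 30 + "TC")
print("L =", circ.L, "L % 3 =", circ.L % 3)
for orf in find_orfs(circ, min_nt_length=30):
    print(orf.orf_id, "start", orf.start_pos, "length", orf.length_label(),
          "laps", orf.laps, "peptide", orf.peptide[:12] + "...")
print("motifs:", [(h.motif_start, h.pentamer, h.kind) for h in scan_motifs(circ)])
```

prints

```
L = 100 L % 3 = 1
ORF1 start 0 length 300 × n laps 3 peptide MGLAAAAAAAAA...
motifs: [(3, 'GGACT', 'BOTH')]
```

The 100-nt circle is not divisible by 3, so its single codon orbit has
period 300 nt. The orbit contains an ATG but no stop codon in any pass,
so the call is an infinite (rolling-circle) ORF: its length field reads
"300 × n" (one repeat unit is 3L = 300 nt, crossing the junction 3
times per lap cycle) and the peptide shown is one repeat unit. The
scanner finds one m6A consensus motif, `GGACT` at position 3, whose
first base G satisfies both D and R — hence kind `BOTH` (every RRACH
site is also a DRACH site); the methylated A sits at position 5.

Training and applying an IRES model from the command line:

```sh
circtrans fixtures --kind ires --n-pos 200 --n-neg 200 --seed 0 --out fx/
circtrans ires-train --pos fx/positives.fasta --neg fx/negatives.fasta \
    --out model.json --seed 0
circtrans ires-predict --in circs.fasta --model model.json --out results/
```

`ires.tsv` lists each positive fragment (`circ_id`, `frag_start`,
`frag_end`, `score`, `spans_junction`); `orfs.tsv` carries each ORF's
assigned IRES, with `None` when no fragment scores above threshold.

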