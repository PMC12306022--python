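# isomotif

Sequence-, annotation- and backbone-topology-independent search of
nucleic-acid **tertiary motifs** in 3D structures.

Structural biologists who want every instance of a module like the
kink-turn in a set of RNA/DNA structures usually depend on sequence
consensus or base-pair annotations — both of which vary far more across
motif instances than the 3D arrangement itself does. `isomotif` searches
directly in coordinate space: given one reference module and any number
of query structures (PDB or mmCIF; files, folders or glob masks), it
reports every set of query residues that is *isosteric* to the
reference — superimposable within an RMSD threshold — no matter its
sequence, annotated pairs or how the backbone is threaded through it.

## Method in brief

For a reference of N residues and a query of M residues, each of the
N·M residue pairs seeds a rigid superposition: 5-atom residue frames
(base atoms N9/N1, C2, C6/C4 + ribose C1' + phosphate P) are fitted by
the Kabsch algorithm. Under each placement, residues are paired by
**mutual-closest matching** of 3-atom base-triad centroids within a
cutoff, the pairing is refined ICP-style (refit on matched triads,
re-match, iterate to a fixed point), and the match is reported with its
size |pairs| and base-triad RMSD if it satisfies

* `sizemin` ≤ size ≤ `sizemax`, RMSD ≤ `rmsdmax`, and
* optional restraints: required positions, IUPAC base patterns,
  subset RMSD, and strand continuity (O3'(i)–P(i+1) < 2.0 Å).

Sub-matches can be removed (`--nosub`), hits from several references
merged into unique matches, and hit sets scored against ground truth
with precision = TP/(TP+FP), recall = TP/(TP+FN),
F = 2·TP/(2·TP+FP+FN). See `docs/methods.md` for the full treatment.

## Worked example

The package ships a synthetic generator (no downloads needed): a
14-residue two-stem module with a sharp bend, a 60-residue query
embedding a rigid copy of it, and a straight-duplex decoy.

    $ isomotif fixtures -o demo && cd demo
    $ isomotif search -r kink_ref.pdb -q kink_positive.pdb \
          --sizemin 12 --rmsdmax 2.0 --labels kink_labels.tsv --nosub

    reference     query              seed     size  rmsd         kink_label  pairs
    kink_ref.pdb  kink_positive.pdb  K.1:M.1  14    0.000611304  kink        K.1:M.1,K.2:M.2,...,L.7:N.7

Reading the row: from the seed pairing of reference residue K.1 onto
query residue M.1, the search matched all 14 module residues at a
base-triad RMSD of 0.0006 Å (the embedded copy is exact; the residual
is PDB coordinate precision), and the partners of positions 2b and L1
are 1 residue apart in sequence, so the hit is labelled a kink. Running
the same search against `kink_decoy.pdb` prints a header and no rows:
a straight duplex contains no 12-residue superimposable copy of the
bent module under a 2.0 Å threshold.

Searching a real database works the same way, e.g. with the kink-turn
configuration documented in `examples/kink_turn/` (reference modules
from PDB entries 1FFK and 3D2G, `--sizemin 12 --rmsdmax 2.0`, a
required-position restraint on the seven core positions, `--nosub`);
`isomotif fetch` downloads entries by accession.

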