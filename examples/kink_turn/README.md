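# Kink-turn / k-junction search configuration

This folder documents the search protocol for locating kink-turn-family
modules in RNA structure databases with `isomotif`. It ships no
coordinate data: the reference entries are fetched from the wwPDB on
demand.

## Reference modules

Two reference instances cover the known backbone-topology variants:

| module | entry, chain | description | anchor residues |
|---|---|---|---|
| canonical kink-turn (Kt7, internal loop) | 1FFK, chain `0` | LSU rRNA | L1 = G94, 1n = A80 |
| k-junction (three-way junction) | 3D2G, chain `A` | TPP riboswitch | L1 = C38, 1n = A72 |

Each module comprises the 14 labelled positions
`L1, L1p, -1b, -1n, -2b, -2n, 1b, 1n, 2b, 2n, 3b, 3n, 4b, 4n`
(`L1p` is absent in the canonical internal-loop variant, which therefore
contributes 13 residues). The full residue lists are a curation choice:
starting from the anchors above, take the two stem base pairs on each
side of the bulge plus the loop residues, and pass them as a `--rres`
selector (e.g. `0/93-97,77-81,...` — chain/number ranges).

## Fetching the references

    isomotif fetch 1FFK 3D2G --out refs/

## Search parameters

Calibrate by searching one reference against the other; the two modules
superimpose as a 13-residue match (L1p has no counterpart) just under
2 Å RMSD, which motivates the thresholds:

    isomotif search \
        -r refs/1ffk.cif --rres '0/<14-residue selection>' \
        -q 'database/*.cif' \
        --sizemin 12 --rmsdmax 2.0 \
        --rst kink_turn.rst --nosub \
        -o kink_turn_hits.tsv

`kink_turn.rst` requires the match to include the counterparts of the
seven core positions (L1, -1b, -1n, 1b, 1n, 2b, 2n); edit the residue
numbers to your selected reference residues. Hits can then be annotated
with the kink/no-kink sequence-distance heuristic via `--labels` and
merged across the two references with
`isomotif.postprocess.deduplicate_across_references`.

Database-wide surveys (every RNA-containing PDB entry) use exactly this
configuration, fanned out over `--threads` and a folder of mmCIF files;
they are hour-scale jobs, not test material.
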