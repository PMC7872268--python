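# protmod

A scriptable homology-modelling toolbox: peptide backbones with
synchronized Cartesian/internal coordinates, CCD loop closure, fragment
databases indexed by stem geometry, knowledge-based statistical potentials,
combinatorial sidechain packing (DEE, edge decomposition, tree-decomposition
DP, A*, Monte Carlo, sub-rotamer optimization) and an end-to-end
`build-model` pipeline from a target–template alignment.

## Layout

| module                | contents |
|-----------------------|----------|
| `protmod.io_formats`  | PDB / minimal mmCIF reading, PDB writing, FASTA alignments, alignment↔chain attachment |
| `protmod.backbone`    | `BackboneList` (N, Cα, C, O, Cβ + φ/ψ/ω), torsion edits, Kabsch superposition, CCD closure |
| `protmod.fragdb`      | `StructureDB` linear store, 3-state secondary structure, six-descriptor stem geometry, `FragDB` hash index, sliding-window fragment search |
| `protmod.scoring`     | scoring environment + spatial hash, cbeta / reduced / cb_packing / torsion / clash / hbond / constraint scorers, inverse-Boltzmann training, weight fitting |
| `protmod.sidechain`   | rotamer libraries (Dunbrack-2010 bbdep dialect + bundled mini library), rigid/flexible rotamers, SCWRL3-style repulsion, disulfide detection, packing solvers, χ1/clash metrics |
| `protmod.modelling`   | raw model from alignment, deletion relaxation, gap elongation, database + Monte-Carlo loop filling, regularizer, full pipeline |
| `protmod.fixtures`    | deterministic synthetic structures, loop cases, decoy sets, mini databases |

## CLI

```bash
# build a model from an alignment (row 0 = target, row 1 = template) and a
# template structure (PDB or mmCIF)
pm3 build-model -f alignment.fasta -e template.pdb -o model.pdb --seed 1

# with fragment databases for database-driven loop modelling
pm3 build-db manifest.tsv -o dbs --lengths 3-14     # manifest: pdb<TAB>chain[<TAB>seqres.fasta]
pm3 build-model -f alignment.fasta -e template.cif -o model.pdb --db-dir dbs

# synthetic fixture structures
pm3 make-fixture toy_protein -n 24 --seed 1 -o toy.pdb
```

Exit codes: 0 success, 1 modelling error (unresolvable gaps), 2 I/O or
format error.

## Library example

```python
from protmod import fixtures
from protmod.modelling import (PipelineConfig, build_raw_model,
                               build_from_raw_model)
from protmod.io_formats import Alignment, attach_view
from protmod.sidechain import load_mini_library

template_bb = fixtures.helix_loop_helix(30, seed=10)
template = fixtures.structure_from_backbone(template_bb)
aln = Alignment([template_bb.sequence, template_bb.sequence])
attach_view(aln, 1, template, "A")
mh = build_raw_model(aln)                  # partial model + gap list
model = build_from_raw_model(mh, PipelineConfig(seed=1),
                             load_mini_library())
```

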