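# rxngrow

Reaction-rule-driven fragment growing for structure-based lead optimization.
A posed query ligand is grown inside a receptor pocket toward user-chosen
interaction sites; every growth step is a virtual application of a reaction
rule extracted from atom-mapped chemistry, so each proposed compound carries
a concrete synthetic route.

## Pipeline

1. **Rule extraction** (`rxngrow.rule_extraction`) — atom-mapped reactions
   are diffed atom-by-atom to find the *reaction core* (atoms whose element,
   charge, aromaticity, neighbor count, or bonding changes), which is then
   extended outward until each growth direction hits an sp³ carbon (included,
   substitution allowed there) or absorbs a whole aromatic ring.  The
   reactant moieties + product moiety + map correspondence form a reusable
   rule.
2. **Block library** (`rxngrow.block_library`) — building blocks are indexed
   per (rule, reactant slot); seed blocks are those containing the
   user-preserved fragment of the query ligand.
3. **Virtual synthesis** (`rxngrow.virtual_synthesis`) — a matched molecule
   is *clipped* into moiety + remainder; the product is the product moiety
   with the reactant and participant remainders re-attached through the map
   correspondence.  Atoms inherited from the posed reactant keep their 3D
   coordinates.
4. **Pose evaluation** (`rxngrow.pose_eval`) — conformer ensembles (default
   30, ETKDG, soft-restrained to the inherited pose), rigid alignment onto
   the preserved space by Gaussian-volume overlap, a deterministic
   piecewise-linear H-bond / hydrophobic / clash scorer, and incremental
   *group efficiency* (Δenergy / Δheavy-atoms).
5. **Growth engine** (`rxngrow.growth_engine`) — beam search (default width
   3; width 1 is pure greedy) over growth states: per interaction target,
   products are enumerated, their best conformer passing the
   direction-of-growth check is kept, and a step is accepted only when its
   group efficiency is strictly below −0.1.  Final candidates are filtered
   (MW < 600, cLogP < 5, both strict), locally refined, ranked by energy,
   and exported with replayable synthetic routes.
6. **Fixtures** (`rxngrow.fixtures`) — a deterministic toy reaction set
   (10 mapped reactions), ~50 building blocks, and a synthetic pocket built
   around a planted 3-step route whose product is verified at generation
   time (by exhaustive enumeration) to be the unique refined-energy optimum.

## CLI

```bash
# write the toy dataset (reactions.smi, blocks.smi, pocket.json, query.sdf)
rxngrow fixtures --out fixtures/ --seed 0

# extract rules (+ block index) to JSON
rxngrow rules --reactions fixtures/reactions.smi --blocks fixtures/blocks.smi \
    --out fixtures/rules.json

# run the growth pipeline
cat > fixtures/config.yaml <<EOF
reactions: reactions.smi
blocks: blocks.smi
pocket: pocket.json
n_conformers: 8
beam: 3
seed: 2024
out_dir: out
EOF
rxngrow grow --config fixtures/config.yaml
# -> fixtures/out/candidates.sdf (ranked, tagged) and fixtures/out/routes.json
```

Config keys and defaults: `n_conformers` 30, `ge_threshold` −0.1, `mw_max`
600, `clogp_max` 5, `beam` 3, `seed` 2024, `steps_per_target` 2.  An optional
`query_sdf` + `fragment_smiles` pair overrides the preserved fragment stored
in `pocket.json`.

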