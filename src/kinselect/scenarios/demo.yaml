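chrom_lengths:
  chr1: 60000000
  chr2: 50000000
  chr3: 40000000
n_variants: 6000
spacing: uniform
fst: 0.2
anc_freq_range:
- 0.05
- 0.95
recomb_rate: 1.04
missing_rate: 0.02
genotype_error_rate: 0.001
seed: 17
pedigree:
- id: IN_f0
  sex: male
  pop: A
  subpopulation: HERD-IN
- id: IN_f1
  sex: female
  pop: A
  subpopulation: HERD-IN
- id: IN_f2
  sex: male
  pop: A
  subpopulation: HERD-IN
- id: IN_g1a
  sex: male
  father: IN_f0
  mother: IN_f1
  subpopulation: HERD-IN
- id: IN_g1b
  sex: female
  father: IN_f0
  mother: IN_f1
  subpopulation: HERD-IN
- id: IN_g1c
  sex: female
  father: IN_f2
  mother: IN_f1
  subpopulation: HERD-IN
- id: IN_g2a
  sex: male
  father: IN_g1a
  mother: IN_g1b
  subpopulation: HERD-IN
- id: IN_g2b
  sex: female
  father: IN_g1a
  mother: IN_g1b
  subpopulation: HERD-IN
- id: IN_g2c
  sex: male
  father: IN_g1a
  mother: IN_g1c
  subpopulation: HERD-IN
- id: IN_g2d
  sex: female
  father: IN_g1a
  mother: IN_g1c
  subpopulation: HERD-IN
- id: OUT_f0
  sex: male
  pop: B
  subpopulation: HERD-OUT
- id: OUT_f1
  sex: female
  pop: B
  subpopulation: HERD-OUT
- id: OUT_f2
  sex: male
  pop: B
  subpopulation: HERD-OUT
- id: OUT_f3
  sex: female
  pop: B
  subpopulation: HERD-OUT
- id: OUT_f4
  sex: male
  pop: B
  subpopulation: HERD-OUT
- id: OUT_f5
  sex: female
  pop: B
  subpopulation: HERD-OUT
- id: OUT_f6
  sex: male
  pop: B
  subpopulation: HERD-OUT
- id: OUT_f7
  sex: female
  pop: B
  subpopulation: HERD-OUT
- id: OUT_f8
  sex: male
  pop: B
  subpopulation: HERD-OUT
- id: OUT_f9
  sex: female
  pop: B
  subpopulation: HERD-OUT
- id: OUT_f10
  sex: male
  pop: B
  subpopulation: HERD-OUT
- id: OUT_f11
  sex: female
  pop: B
  subpopulation: HERD-OUT
- id: OUT_g0
  sex: male
  father: OUT_f0
  mother: OUT_f1
  subpopulation: HERD-OUT
- id: OUT_g1
  sex: female
  father: OUT_f2
  mother: OUT_f3
  subpopulation: HERD-OUT
- id: OUT_g2
  sex: male
  father: OUT_f4
  mother: OUT_f5
  subpopulation: HERD-OUT
- id: OUT_g3
  sex: female
  father: OUT_f6
  mother: OUT_f7
  subpopulation: HERD-OUT
- id: OUT_g4
  sex: male
  father: OUT_f8
  mother: OUT_f9
  subpopulation: HERD-OUT
- id: OUT_g5
  sex: female
  father: OUT_f10
  mother: OUT_f11
  subpopulation: HERD-OUT
- id: HYB_a
  sex: male
  pop: A
  subpopulation: HYB
- id: HYB_b
  sex: female
  pop: B
  subpopulation: HYB
- id: HYB_f1
  sex: female
  father: HYB_a
  mother: HYB_b
  subpopulation: HYB
- id: HYB_bc
  sex: male
  father: OUT_f0
  mother: HYB_f1
  subpopulation: HYB
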