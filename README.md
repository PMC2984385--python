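# ldlmap

Fine-mapping a quantitative trait locus (QTL) in half-sib animal designs —
the family structure typical of cattle and other livestock breeding
programs, where a few sires each have tens to hundreds of progeny from
unrelated dams.

Given a dense map of phased bi-allelic SNP haplotypes and one phenotype
per progeny, `ldlmap` implements and compares two scans that differ in how
they model the linkage disequilibrium (LD) between the QTL and its
flanking markers:

* **HaploMax** — a haplotype-dose association scan.  In every marker
  interval and for each observed flanking-marker haplotype *h*, it fits

  ```
  y_ij = sire_i + γ · dose_h(ij) + e_ij ,   dose_h ∈ {0, 1, 2}
  ```

  and takes the maximum 1-df F statistic for γ over haplotypes; the
  estimated QTL position is the midpoint of the best interval.  LD is
  implicitly assumed complete and constant: the causal allele is presumed
  to sit on one haplotype, forever.

* **HAPimLDL** — a likelihood that combines linkage with probabilistic
  modelling of LD *evolution*.  The phenotype of progeny *ij* is a
  Gaussian mixture over the unobserved QTL states:

  ```
  Λ_ij(x) = Σ_z P(Z_i = z | h_i) Σ_a P(Q^d_ij = a | h^d_ij)
            [ φ(y_ij; μ_i + α_Qa, σ²) P(sire transmits Q)
            + φ(y_ij; μ_i + α_qa, σ²) P(sire transmits q) ]
  ```

  with `z` over the four ordered sire diplotypes, `a` the dam-transmitted
  allele, and the sire-transmission term built from the chromosome-of-origin
  probabilities at `x` given the flanking-marker origins.  The conditional
  allele probabilities `P(Q | h) = min(1, E[Π_{Q,h}(t)] / E[Π_h(t)])` come
  from a Wright–Fisher model: Bennett multilocus disequilibria decay
  geometrically at the no-recombination probability of their loci, starting
  from a time-0 state in which the mutation arose on one founder haplotype
  (`Π_{h,Q}(0) = (1−β) Π_h Π_Q(0) + β Π_Q(0) δ_{h=h*}`, with β = 1).
  The scan maximizes the summed log-likelihood per tested position over the
  sire means, the additive effect α (α_QQ = −α_qq, heterozygote effects 0),
  σ², the founder haplotype `h*` and `Π_Q(0)`, and reports the
  likelihood-ratio profile.

A gene-dropping forward simulator (`ldlmap.simdesign`) generates the study
populations — a founder population of effective size `Ne` evolving `Ng`
Wright–Fisher generations with Haldane crossovers, optional truncation
selection and marker mutation, then a half-sib design sampled from the
final generation — and `ldlmap.evaluate` measures positional accuracy
(root mean squared error of the estimated position, in cM) and power
against within-family permutation thresholds over replicates.

## Worked example

```python
import numpy as np
from ldlmap import Scenario, simulate_design, haplomax_scan, ldl_scan

# reference conditions: 40 SNPs over 10 cM, Ne=100, 50 generations after
# the causal mutation, 20 sires x 100 progeny, substitution effect 0.25
scenario = Scenario()
design = simulate_design(scenario, np.random.default_rng(7))

hm = haplomax_scan(design, n_flanking=2)
print(f"HaploMax:  s_hat = {hm.s_hat:.3f} cM  (max F = {hm.max_statistic:.2f})")

ldl = ldl_scan(design, t=scenario.n_generations)
print(f"HAPimLDL:  s_hat = {ldl.s_hat:.3f} cM  (max LRT = {ldl.max_statistic:.2f})")
print(f"true QTL position: {design.gmap.qtl_position} cM")
```

Output:

```
HaploMax:  s_hat = 5.625 cM  (max F = 4.78)
HAPimLDL:  s_hat = 5.625 cM  (max LRT = 5.20)
true QTL position: 3.35 cM
```

Both scans test every marker-interval midpoint; on this replicate both
peak 2.3 cM from the true position — single replicates are noisy (the
modest QTL effect of 0.25 phenotypic SD explains only ~3% of the
variance), which is why accuracy is summarized as root-MSE over many
replicates (about 2 cM for both methods under these conditions).

The same workflow is available from the shell:

```
ldlmap simulate --seed 7 --out sim/
ldlmap scan-haplomax --map sim/map.tsv --haps sim/haplotypes.tsv \
    --phen sim/phenotypes.tsv --window 2 --out scan.tsv
ldlmap scan-ldl --map sim/map.tsv --haps sim/haplotypes.tsv \
    --phen sim/phenotypes.tsv --window 2 --generations 50 --out ldl.tsv
ldlmap replicate --method haplomax --reps 100 --seed 1 --out table.tsv
```

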