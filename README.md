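# vhhforge

Analysis pipeline for single-domain antibody (VHH) projects, exercised
end-to-end on ground-truthed synthetic data:

- **`synthetic_data`** — generators for every pipeline input: VHH
  repertoires with zero-truncated negative-binomial read counts, Gaussian
  translated lengths and a controlled defective fraction; a toy two-domain
  antigen/antibody complex; docked-pose ensembles with planted clusters and
  planted outliers (optionally contact-docked so they survive interface
  filtering).
- **`repertoire`** — full-length filtering (frameshift / premature-stop /
  length), cardinality (counts-of-counts) spectra, maximum-likelihood
  zero-truncated negative-binomial diversity estimation with the
  U / (1 − p0) unseen-species extrapolation, and Gaussian length fits.
- **`annotation`** — CDR1/2/3 localisation on VHH amino-acid sequences by
  framework anchor motifs (conserved Cys pair, FR2 Trp, FR4 WGxG), with
  manual spans as the escape hatch.
- **`structure`** — PDB I/O, Kabsch superposition, Shrake–Rupley SASA on a
  deterministic Fibonacci sphere lattice, per-residue ensemble RMSD.
- **`docking`** — per-pose interface extraction (strict < 4 Å all-atom
  cutoff), two-stage CDR-contact filtering (≥ 10 interacting CDR residues
  by default), pairwise interface RMSD after antigen superposition, DBSCAN
  on the precomputed matrix (eps = 9 Å, min_samples = 3 defaults) with
  core/reachable/outlier status, cluster composition summaries, optional
  t-SNE embedding.
- **`solubility`** — exposed-hydrophobic flagging outside CDRs
  (relative-SASA threshold) and deterministic substitution suggestions
  (I/L/V → A, M/F/W → K).

## CLI

Everything is reachable through the `forge` command:

```sh
# synthetic inputs (seed mandatory; same seed -> identical output)
forge simulate repertoire --n-unique 5000 --defect-fraction 0.07 --seed 1 --out lib.fasta
forge simulate poses --n-clusters 3 --sizes 8,6,5 --n-outliers 4 \
    --min-between-separation 40 --outlier-min-separation 15 --seed 1 --out poses/

# repertoire statistics
forge repertoire --in lib.fasta --min-aa 90 --max-aa 150 --out report.json

# CDR annotation
forge annotate --in vhh.fasta --mode motif --out ann.json

# structural analyses
forge sasa --pdb model.pdb --out sasa.tsv
forge ensemble-rmsd --pdb traj.pdb --align "B:1-121" --atoms N,CA,C --stride 10 --out rmsd.tsv

# docked-pose ensemble pipeline: contacts -> filters -> iRMSD -> DBSCAN
forge dock-analyze --poses poses/manifest.tsv --ann poses/annotation.json \
    --domains poses/domains.json --cutoff 4.0 --min-cdr 10 --eps 9 --min-samples 3 \
    --out analysis/

# solubility engineering suggestions
forge solubility --pdb model.pdb --chain B --ann ann.json --rel-sasa-min 0.30 --out mut.tsv
```

## Notes

- Coordinates for CDR spans are 0-based half-open internally; reports also
  print 1-based inclusive.
- DBSCAN reads `min_samples` with the point counting itself (the common
  library convention); border ties break deterministically to the lowest
  cluster label.
- Cluster composition tables are a starting point: docking artefacts (e.g.
  chain-threading poses) still require manual review before biological
  interpretation.
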