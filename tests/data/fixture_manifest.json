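{
  "checksums": {
    "cohort.vcf": "aa52f64cf12b4f80b1751fcaab93f94a3befc03b6c44c0d24048117ede388070",
    "fst.CMP.tsv": "76e49207f0ffc16a19e6404f7ce93b2f0bae78889eab767c372e85a777d52f06",
    "fst.SEL.tsv": "dc58a67a011ed7f8788b3d28a601d3af5199df9fba8032826034b8304df3602f",
    "genes.gff3": "4d8053011178850c8487449cafed0569d58ea6aba6cd61005bca740e9c5f4830",
    "rdd_genes.tsv": "57903098178699bf64e2bb4f633c87fb416acd4055b97e6ec74a5a539a5f5468",
    "rdd_regions.bed": "e3b0c44298fc1c149afbf4c8996fb92427ae41e4649b934ca495991b7852b855",
    "rdd_windows.tsv": "944f2cc4ee6fa1417158f957718743f62c847a384b784c78e2e67d54ae41943d",
    "samples.tsv": "6db85f880f63c6b2dc2fcb0dd0cc5a8489171330a4e437155212151ea450a80b",
    "sites.tsv": "3902c512eacbe7ecebc7a3e139f7a5091e450e594ff4ecf208877502522b71a8",
    "terms.gmt": "f025aac33109cf46740b386b150913cbca816199839a90bf4945b9a9c126457e",
    "truth_freqs.tsv": "4a03706515592b10185ae5559304957d2d579300970c0906520d5a2735f299d3",
    "truth_regions.bed": "6e27c802ad16f31e2654f31afbdab9cc1bf54e637726284ee7031fdf6b55e6e3",
    "windows.CMP.tsv": "50ce8b72d09105487ad3e4b2241cf6dce448ff145b93632d0588385705f7700e",
    "windows.SEL.tsv": "4e9751b89be58088b447dd610203bcd83b08228a32fec71fda7cae5cb935192b"
  },
  "counts": {
    "eligible_windows": 32,
    "genes_overlapping": {
      "non_coding": 0,
      "protein_coding": 0,
      "total_genes": 0
    },
    "merged_regions": 0,
    "rdd_windows": 0,
    "sites_excluded_per_contrast": {
      "CMP": {
        "monomorphic_or_degenerate": 100,
        "no_called_samples": 0
      },
      "SEL": {
        "monomorphic_or_degenerate": 111,
        "no_called_samples": 0
      }
    },
    "sites_read": 800,
    "sites_skipped": {
      "filtered": 0,
      "multiallelic": 0,
      "not_snp": 0
    },
    "terms_tested": 0,
    "windows_built": 32,
    "windows_retained_per_contrast": {
      "CMP": 32,
      "SEL": 32
    }
  }
}
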