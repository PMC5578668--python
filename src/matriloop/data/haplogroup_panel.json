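{
 "haplogroups": {
  "A": [
   [
    {
     "allele": "C",
     "position": 15495
    },
    {
     "allele": "T",
     "position": 15602
    },
    {
     "allele": "A",
     "position": 15720
    },
    {
     "allele": "G",
     "position": 15826
    },
    {
     "allele": "T",
     "position": 15870
    },
    {
     "allele": "G",
     "position": 15956
    },
    {
     "allele": "T",
     "position": 15974
    },
    {
     "allele": "C",
     "position": 16371
    }
   ]
  ],
  "D3": [
   [
    {
     "allele": "C",
     "position": 15495
    },
    {
     "allele": "A",
     "position": 15666
    },
    {
     "allele": "A",
     "position": 15720
    },
    {
     "allele": "G",
     "position": 15826
    },
    {
     "allele": "G",
     "position": 16057
    },
    {
     "allele": "C",
     "position": 16371
    }
   ],
   [
    {
     "allele": "C",
     "position": 15495
    },
    {
     "allele": "A",
     "position": 15666
    },
    {
     "allele": "A",
     "position": 15720
    },
    {
     "allele": "G",
     "position": 16057
    },
    {
     "allele": "C",
     "position": 16371
    }
   ]
  ],
  "F": [
   [
    {
     "allele": "C",
     "position": 15495
    },
    {
     "allele": "C",
     "position": 15601
    },
    {
     "allele": "T",
     "position": 15602
    },
    {
     "allele": "A",
     "position": 15720
    },
    {
     "allele": "T",
     "position": 15771
    },
    {
     "allele": "T",
     "position": 15806
    },
    {
     "allele": "G",
     "position": 15827
    },
    {
     "allele": "T",
     "position": 15838
    },
    {
     "allele": "T",
     "position": 15869
    },
    {
     "allele": "G",
     "position": 15956
    },
    {
     "allele": "C",
     "position": 16009
    },
    {
     "allele": "C",
     "position": 16071
    },
    {
     "allele": "C",
     "position": 16371
    },
    {
     "allele": "A",
     "position": 16543
    },
    {
     "allele": "C",
     "position": 16546
    },
    {
     "allele": "T",
     "position": 16559
    },
    {
     "allele": "G",
     "position": 16635
    }
   ]
  ],
  "I": [
   [
    {
     "allele": "C",
     "position": 15495
    },
    {
     "allele": "G",
     "position": 15538
    },
    {
     "allele": "T",
     "position": 15602
    },
    {
     "allele": "T",
     "position": 15709
    },
    {
     "allele": "A",
     "position": 15720
    },
    {
     "allele": "T",
     "position": 15771
    },
    {
     "allele": "G",
     "position": 15826
    },
    {
     "allele": "T",
     "position": 15870
    },
    {
     "allele": "T",
     "position": 15974
    },
    {
     "allele": "C",
     "position": 16371
    },
    {
     "allele": "T",
     "position": 16442
    }
   ]
  ],
  "K3": [
   [
    {
     "allele": "C",
     "position": 15495
    },
    {
     "allele": "T",
     "position": 15602
    },
    {
     "allele": "G",
     "position": 15667
    },
    {
     "allele": "C",
     "position": 15703
    },
    {
     "allele": "A",
     "position": 15720
    },
    {
     "allele": "T",
     "position": 15771
    },
    {
     "allele": "G",
     "position": 15777
    },
    {
     "allele": "G",
     "position": 15809
    },
    {
     "allele": "G",
     "position": 15956
    },
    {
     "allele": "G",
     "position": 16040
    },
    {
     "allele": "C",
     "position": 16371
    },
    {
     "allele": "A",
     "position": 16543
    },
    {
     "allele": "G",
     "position": 16635
    }
   ]
  ],
  "X2": [
   [
    {
     "allele": "C",
     "position": 15494
    },
    {
     "allele": "C",
     "position": 15495
    },
    {
     "allele": "G",
     "position": 15496
    },
    {
     "allele": "T",
     "position": 15534
    },
    {
     "allele": "T",
     "position": 15602
    },
    {
     "allele": "C",
     "position": 15603
    },
    {
     "allele": "G",
     "position": 15649
    },
    {
     "allele": "A",
     "position": 15720
    },
    {
     "allele": "T",
     "position": 15771
    },
    {
     "allele": "T",
     "position": 15807
    },
    {
     "allele": "T",
     "position": 15870
    },
    {
     "allele": "T",
     "position": 15871
    },
    {
     "allele": "G",
     "position": 15956
    },
    {
     "allele": "T",
     "position": 15974
    },
    {
     "allele": "C",
     "position": 16068
    },
    {
     "allele": "G",
     "position": 16079
    },
    {
     "allele": "C",
     "position": 16371
    }
   ]
  ],
  "X3": [
   [
    {
     "allele": "C",
     "position": 15495
    },
    {
     "allele": "T",
     "position": 15542
    },
    {
     "allele": "T",
     "position": 15602
    },
    {
     "allele": "T",
     "position": 15635
    },
    {
     "allele": "A",
     "position": 15666
    },
    {
     "allele": "T",
     "position": 15703
    },
    {
     "allele": "A",
     "position": 15720
    },
    {
     "allele": "T",
     "position": 15870
    },
    {
     "allele": "C",
     "position": 16371
    }
   ]
  ],
  "X3c1": [
   [
    {
     "allele": "C",
     "position": 15495
    },
    {
     "allele": "T",
     "position": 15542
    },
    {
     "allele": "T",
     "position": 15602
    },
    {
     "allele": "T",
     "position": 15635
    },
    {
     "allele": "A",
     "position": 15666
    },
    {
     "allele": "C",
     "position": 15703
    },
    {
     "allele": "A",
     "position": 15720
    },
    {
     "allele": "T",
     "position": 15870
    },
    {
     "allele": "C",
     "position": 16033
    },
    {
     "allele": "C",
     "position": 16371
    }
   ]
  ]
 },
 "metadata": {
  "nomenclature": "Cieslak-style equine haplogroup labels (A-K, X1-X8)",
  "note": "minimal demonstration panel reconstructed from the study's haplotype-to-haplogroup pairs; supply an authoritative motif catalogue for de novo data"
 }
}
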