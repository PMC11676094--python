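metabolite,comparison,r
Acetone,urine_24h,-0.774
Adenosine,lung_48h,0.773
Allantoic acid,lung_48h,-0.815
Allantoin,brain_48h,-0.846
Allantoin,liver_48h,-0.758
Alpha-glucose,brain_48h,-0.795
Alpha-glucose,plasma_48h,-0.904
Beta-glucose,plasma_48h,-0.871
Creatine,brain_48h,0.868
Creatinine,brain_48h,0.795
Ethanolamine,kidney_48h,0.762
gamma-Aminobutyrate,brain_48h,0.766
Glutamate,brain_48h,0.797
Glutamate,liver_48h,-0.774
Glycerophosphocholine,brain_48h,-0.791
Glycogen,brain_48h,-0.791
Guanosine,liver_48h,-0.832
Guanosine,lung_48h,0.830
Lactate,brain_48h,0.862
Lactate,plasma_48h,0.907
Leucine,brain_48h,-0.803
N-acetylaspartate,brain_48h,0.901
NAD+,brain_48h,-0.767
NAD+,liver_48h,-0.834
NADP+,liver_48h,-0.822
Nicotinamide N-oxide,urine_24h,0.767
Nicotinate,urine_24h,0.839
Pantothenate,kidney_48h,0.851
Phosphocholine,brain_48h,-0.796
Phosphoethanolamine,brain_48h,-0.882
Succinate,urine_48h,-0.806
Taurine,brain_48h,-0.797
Threonine,brain_48h,-0.771
Tyrosine,kidney_48h,0.791
Uracil,kidney_48h,0.786
Valine,brain_48h,-0.791
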