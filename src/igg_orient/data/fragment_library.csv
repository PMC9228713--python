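label,nominal_mass,amino_acid,enrichment_class
CH4N+,30,glycine,substrate
C2H5S+,61,methionine,substrate
C4H6N+,68,proline,Fc
C4H8N+,70,proline,Fc
CH5N3+,59,arginine,Fc
C4H10N3+,100,arginine,Fc
C4H5N2+,81,histidine,Fc
C5H8N3+,110,histidine,Fc
C7H7+,91,phenylalanine,Fc
C8H10N+,120,phenylalanine,Fc
C2H6N+,44,alanine,Fab
C2H6NO+,60,serine,Fab
C2H4NO+,58,serine,Fab
C3H8NO+,74,threonine,Fab
C3H5O+,57,threonine,Fab
C5H12N+,86,leucine,Fab
C5H9+,69,leucine,Fab
C4H10N+,72,valine,neutral
C4H7+,55,valine,neutral
C5H10N+,84,lysine,neutral
C3H6N+,56,lysine,neutral
C2H6NS+,76,cysteine,neutral
C2H3S+,59,cysteine,neutral
C4H10NS+,104,methionine,neutral
C3H6NO2+,88,aspartate,neutral
C4H8NO2+,102,glutamate,neutral
C3H7N2O+,87,asparagine,neutral
C4H9N2O+,101,glutamine,neutral
C4H6NO+,84,glutamine,neutral
C7H7O+,107,tyrosine,neutral
C8H10NO+,136,tyrosine,neutral
C9H8N+,130,tryptophan,neutral
C10H11N2+,159,tryptophan,neutral
C11H8NO+,170,tryptophan,neutral
CH2N+,28,glycine,neutral
C4H6N2+,82,histidine,neutral
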