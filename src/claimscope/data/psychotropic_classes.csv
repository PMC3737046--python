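class,atc_prefix,note
antidepressant,N06A,all antidepressants
mood_stabilizer,N03A,antiepileptics used as mood stabilizers
mood_stabilizer,N05AN01,lithium
anxiolytic,N05B,anxiolytics
adhd_medication,N06BA,psychostimulants and atomoxetine
adhd_medication,C02AC01,clonidine
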