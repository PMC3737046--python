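atc,drug_name,generation,formulations
N05AA01,chlorpromazine,FGA,oral
N05AA02,methotrimeprazine,FGA,oral
N05AB02,fluphenazine,FGA,oral|lai
N05AB03,perphenazine,FGA,oral
N05AB06,trifluoperazine,FGA,oral
N05AC01,periciazine,FGA,oral
N05AC02,thioridazine,FGA,oral
N05AC04,pipotiazine,FGA,lai
N05AD01,haloperidol,FGA,oral|lai
N05AF01,flupenthixol,FGA,oral|lai
N05AF04,thiothixene,FGA,oral
N05AF05,zuclopenthixol,FGA,oral|lai
N05AG02,pimozide,FGA,oral
N05AH01,loxapine,FGA,oral
N05AH03,olanzapine,SGA,oral
N05AH04,quetiapine,SGA,oral
N05AX08,risperidone,SGA,oral|lai
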