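group,variable,category,count,n,printed_pct,printed_inconsistent
group1,other_atopic_disorders,A-AD,25,25,100,0
group1,other_atopic_disorders,NA,72,186,39,0
group1,other_atopic_disorders,NA-AD,72,72,100,0
group1,allergic_rhinitis,A-AD,23,25,92,0
group1,allergic_rhinitis,NA,47,186,25,0
group1,allergic_rhinitis,NA-AD,47,72,65,0
group1,atopic_dermatitis,A-AD,8,25,32,0
group1,atopic_dermatitis,NA,12,186,6,0
group1,atopic_dermatitis,NA-AD,12,72,17,0
group1,allergic_conjunctivitis,A-AD,17,25,68,0
group1,allergic_conjunctivitis,NA,26,186,14,0
group1,allergic_conjunctivitis,NA-AD,26,72,36,0
group1,food_allergy,A-AD,5,25,20,0
group1,food_allergy,NA,10,186,5,0
group1,food_allergy,NA-AD,10,72,14,0
group1,drug_allergy,A-AD,5,25,20,0
group1,drug_allergy,NA,14,186,8,0
group1,drug_allergy,NA-AD,14,72,19,0
group1,parental_asthma,A-AD,6,25,24,0
group1,parental_asthma,NA,11,186,6,0
group1,parental_asthma,NA-AD,6,72,8,0
group1,parental_asthma,NA-NAD,5,114,4,0
group1,parental_rhinitis,A-AD,10,25,40,0
group1,parental_rhinitis,NA,36,186,19,0
group1,parental_rhinitis,NA-AD,21,72,29,0
group1,parental_rhinitis,NA-NAD,15,114,13,0
group1,parental_dermatitis,A-AD,3,25,12,0
group1,parental_dermatitis,NA,8,186,4,0
group1,parental_dermatitis,NA-AD,2,72,3,0
group1,parental_dermatitis,NA-NAD,6,114,5,0
group1,antibiotics,A-AD,11,25,44,0
group1,antibiotics,NA,57,186,31,0
group1,antibiotics,NA-AD,22,72,31,0
group1,antibiotics,NA-NAD,35,114,31,0
group1,paracetamol,A-AD,18,25,72,0
group1,paracetamol,NA,107,186,56,1
group1,paracetamol,NA-AD,39,72,54,0
group1,paracetamol,NA-NAD,68,114,60,0
group1,inhaled_corticosteroids,A-AD,2,25,8,0
group1,inhaled_corticosteroids,NA,5,186,3,0
group1,inhaled_corticosteroids,NA-AD,3,72,4,0
group1,inhaled_corticosteroids,NA-NAD,2,114,2,0
group1,injectable_corticosteroids,A-AD,2,25,8,0
group1,injectable_corticosteroids,NA,7,186,4,0
group1,injectable_corticosteroids,NA-AD,6,72,8,0
group1,injectable_corticosteroids,NA-NAD,1,114,1,0
group2,other_atopic_disorders,A-AD,14,14,100,0
group2,other_atopic_disorders,NA,47,111,42,0
group2,other_atopic_disorders,NA-AD,47,47,100,0
group2,allergic_rhinitis,A-AD,14,14,100,0
group2,allergic_rhinitis,NA,34,111,31,0
group2,allergic_rhinitis,NA-AD,34,47,72,0
group2,atopic_dermatitis,A-AD,5,14,36,0
group2,atopic_dermatitis,NA,13,111,12,0
group2,atopic_dermatitis,NA-AD,13,47,28,0
group2,allergic_conjunctivitis,A-AD,8,14,57,0
group2,allergic_conjunctivitis,NA,20,111,18,0
group2,allergic_conjunctivitis,NA-AD,20,47,43,0
group2,food_allergy,A-AD,1,14,7,0
group2,food_allergy,NA,7,111,6,0
group2,food_allergy,NA-AD,7,47,15,0
group2,drug_allergy,A-AD,3,14,21,0
group2,drug_allergy,NA,8,111,7,0
group2,drug_allergy,NA-AD,8,47,17,0
group2,parental_asthma,A-AD,3,14,21,0
group2,parental_asthma,NA,12,111,11,0
group2,parental_asthma,NA-AD,5,47,11,0
group2,parental_asthma,NA-NAD,7,64,11,0
group2,parental_rhinitis,A-AD,7,14,50,0
group2,parental_rhinitis,NA,34,111,31,0
group2,parental_rhinitis,NA-AD,19,47,40,0
group2,parental_rhinitis,NA-NAD,15,64,23,0
group2,parental_dermatitis,A-AD,2,14,14,0
group2,parental_dermatitis,NA,11,111,10,0
group2,parental_dermatitis,NA-AD,6,47,13,0
group2,parental_dermatitis,NA-NAD,5,64,8,0
group2,antibiotics,A-AD,1,14,7,0
group2,antibiotics,NA,32,111,29,0
group2,antibiotics,NA-AD,12,47,26,0
group2,antibiotics,NA-NAD,20,64,31,0
group2,paracetamol,A-AD,8,14,57,0
group2,paracetamol,NA,67,111,60,0
group2,paracetamol,NA-AD,31,47,66,0
group2,paracetamol,NA-NAD,36,64,56,0
group2,inhaled_corticosteroids,A-AD,2,14,14,0
group2,inhaled_corticosteroids,NA,1,111,1,0
group2,inhaled_corticosteroids,NA-AD,1,47,2,0
group2,inhaled_corticosteroids,NA-NAD,0,64,0,0
group2,injectable_corticosteroids,A-AD,0,14,0,0
group2,injectable_corticosteroids,NA,2,111,2,0
group2,injectable_corticosteroids,NA-AD,1,47,2,0
group2,injectable_corticosteroids,NA-NAD,1,64,2,0
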