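odml-version: '1.4'
Document:
  author: Alice
  date: '2000-01-01'
  version: '1.0'
  sections:
  - name: Subject
    type: subject
    id: 5698df91-2db0-47ed-a712-407ef1a378cd
    sections:
    - name: Scores_2000-01-01
      type: scores
      id: 8c6451da-5c37-4b2d-94f7-7e61d4fc4b55
      properties:
      - name: Date
        type: date
        values:
        - '2000-01-01'
        id: 89163033-07cd-48f1-9c44-08d74e10ad22
      - name: Weight
        unit: g
        type: float
        values:
        - 5.0
        id: 5211e6c3-d775-4e77-aa7f-f8ee64c3dc7f
      - name: Experimenter
        type: string
        values:
        - Alice
        id: dd4f0451-4517-475d-bb87-777a15a545dc
      - name: Comment
        type: text
        values:
        - Blood sample was taken [...]
        id: ccb1510c-9836-4f47-848a-ef4756d05ae2
    - name: Scores_2000-01-02
      type: scores
      id: c6f98077-c232-4c3b-a0e7-29657c3c064a
      properties:
      - name: Date
        type: date
        values:
        - '2000-01-02'
        id: 9de4a636-6833-4bea-9a5a-111393f9ddd0
      - name: Weight
        unit: g
        type: float
        values:
        - 5.5
        id: 55cdb427-1725-4c6f-a80b-e9b43d1c4ec7
      - name: Experimenter
        type: string
        values:
        - Bob
        id: a1e3b792-d80b-49c1-b63f-a1827fd2f95f
      - name: Comment
        type: text
        values:
        - Small scratch at the right ear
        id: 65e07dcf-0356-40cb-8c6d-7c39e0c65913
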